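"""End-to-end orchestration: simulate/load → filter → code → combine →
predict → report.

A single :class:`RunConfig` (YAML-loadable) drives every stage; all
stage-level randomness is derived deterministically from the global seed, so
re-running a config reproduces every output byte for byte.  The summary
report collects marker statistics, variance components, heritabilities and
cross-validated accuracies per target × trait × method × coding.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import combability, evalcv, genio, hybridcode, popstruct, simdata
from .core import MatingDesign, PhenotypeTable
from .evalcv import CVPlan
from .genio import FilterSpec
from .gsmodels import ModelSpec

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    seed: int = 0
    outdir: str = "hybridgp_run"
    sim: simdata.SimConfig | None = None
    vcf: str | None = None
    mating: str | None = None
    phenotypes: str | None = None
    filter: FilterSpec = field(default_factory=FilterSpec)
    models: list[ModelSpec] = field(default_factory=lambda: [ModelSpec(method="gblup")])
    cv: CVPlan = field(default_factory=lambda: CVPlan(n_folds=10, n_repeats=2))
    traits: list[str] | None = None
    targets: tuple[str, ...] = ("gca", "hybrid")
    codings: tuple[str, ...] = ("A", "AD")
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        has_files = all(p is not None for p in (self.vcf, self.mating, self.phenotypes))
        if self.sim is None and not has_files:
            raise ValueError("config needs either a sim section or vcf+mating+phenotypes paths")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kw = dict(raw)
        if "sim" in kw and kw["sim"] is not None:
            kw["sim"] = simdata.SimConfig(**kw["sim"])
        if "filter" in kw and kw["filter"] is not None:
            kw["filter"] = FilterSpec(**kw["filter"])
        if "models" in kw:
            kw["models"] = [
                ModelSpec(**{**m, "effect_terms": tuple(m.get("effect_terms", ("additive",)))})
                for m in kw["models"]
            ]
        if "cv" in kw and kw["cv"] is not None:
            kw["cv"] = CVPlan(**kw["cv"])
        for tup in ("targets", "codings"):
            if tup in kw and kw[tup] is not None:
                kw[tup] = tuple(kw[tup])
        return cls(**kw)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    return [int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(seed).spawn(n)]


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute all requested stages; returns the paths written.

    A stage failure raises with the failing stage named; outputs of completed
    stages are left in place.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    seeds = _stage_seeds(config.seed)
    paths: dict[str, Path] = {}
    stage = "setup"
    try:
        # ------------------------------------------------ inputs
        stage = "simulate" if config.sim is not None else "load"
        if config.sim is not None:
            sim_cfg = simdata.SimConfig(**{**config.sim.__dict__, "seed": seeds[0]})
            founders = simdata.simulate_founders(sim_cfg)
            design = simdata.make_design(
                sim_cfg.n_lines, sim_cfg.n_testers, complete=True
            )
            pheno, truth = simdata.simulate_phenotypes(founders, design, sim_cfg)
            sim_paths = simdata.write_simulation(
                founders, design, pheno, truth, out / "sim", overwrite=True
            )
            paths |= {f"sim_{k}": v for k, v in sim_paths.items()}
            inputs = {k: str(v) for k, v in sim_paths.items()}
        else:
            founders = genio.read_vcf(config.vcf)
            design = MatingDesign(table=pd.read_csv(config.mating, sep="\t"))
            pheno = PhenotypeTable(data=pd.read_csv(config.phenotypes, sep="\t"))
            inputs = {
                "vcf": config.vcf,
                "mating": config.mating,
                "phenotypes": config.phenotypes,
            }

        traits = config.traits or pheno.traits

        # ------------------------------------------------ filtering + stats
        stage = "filter"
        if founders.dp is not None or founders.gq is not None:
            founders = genio.mask_low_quality(founders, config.filter)
        filtered, filter_report = genio.filter_markers(founders, config.filter)

        stage = "stats"
        stats = genio.marker_stats(filtered)
        paths["stats"] = out / "marker_stats.tsv"
        genio.write_stats(stats, paths["stats"])

        # ------------------------------------------------ structure tree
        stage = "tree"
        dm = popstruct.ibs_distance(filtered)
        tree = popstruct.upgma(dm)
        paths["tree"] = out / "upgma.nwk"
        popstruct.write_newick(tree, paths["tree"])

        # ------------------------------------------------ codings
        stage = "code"
        parental = hybridcode.code_parents(filtered, seed=seeds[1])
        hyb_a, hyb_d = hybridcode.code_hybrids(filtered, design, seed=seeds[1])

        # ------------------------------------------------ combining ability
        stage = "combine"
        combine_rows, gca_by_trait, blue_by_trait = [], {}, {}
        for trait in traits:
            vc, tab = combability.fit_ncii(pheno, design, trait)
            gca_by_trait[trait] = tab
            blue_by_trait[trait] = tab.blues
            combine_rows.append(
                {
                    "trait": trait,
                    **vc.as_dict(),
                    "H2_gca": combability.gca_heritability(vc),
                    "h2_entry": combability.entry_heritability(pheno, trait),
                }
            )
        combine_df = pd.DataFrame(combine_rows)
        paths["components"] = out / "components.tsv"
        combine_df.to_csv(paths["components"], sep="\t", index=False, float_format="%.6g")
        for trait in traits:
            tab = gca_by_trait[trait]
            gca_df = pd.concat(
                [
                    tab.gca_lines.rename("gca").to_frame().assign(role="line"),
                    tab.gca_testers.rename("gca").to_frame().assign(role="tester"),
                ]
            )
            gca_df.to_csv(out / f"gca_{trait}.tsv", sep="\t", index_label="parent")
            tab.blues.rename("blue").to_csv(
                out / f"blue_{trait}.tsv", sep="\t", index_label="hybrid"
            )

        # ------------------------------------------------ prediction
        stage = "predict"
        acc_rows = []
        line_ids = [s for s in filtered.sample_ids if s in set(design.table["line"])]
        line_rows = [parental.row_ids.index(s) for s in line_ids]
        for trait in traits:
            tab = gca_by_trait[trait]
            y_gca = tab.gca_lines.reindex(line_ids).to_numpy()
            blues = blue_by_trait[trait]
            hyb_ids = [h for h in hyb_a.row_ids if h in blues.index]
            hyb_rows = [hyb_a.row_ids.index(h) for h in hyb_ids]
            y_hyb = blues.reindex(hyb_ids).to_numpy()
            for spec in config.models:
                plan = CVPlan(
                    n_folds=config.cv.n_folds,
                    n_repeats=config.cv.n_repeats,
                    seed=seeds[2],
                )
                if "gca" in config.targets:
                    run = evalcv.run_cv(
                        y_gca,
                        [parental.values[line_rows]],
                        spec,
                        plan,
                        target="gca_line",
                        coding="parental",
                    )
                    acc_rows.append(
                        {
                            "target": "gca_line",
                            "trait": trait,
                            "method": spec.method,
                            "coding": "A",
                            "accuracy": run.accuracy,
                            "sd": run.accuracy_sd,
                        }
                    )
                if "hybrid" in config.targets:
                    runs = {}
                    for coding in config.codings:
                        terms = [hyb_a.values[hyb_rows]]
                        if coding == "AD":
                            terms.append(hyb_d.values[hyb_rows])
                        c_spec = ModelSpec(
                            **{
                                **spec.__dict__,
                                "effect_terms": ("additive", "dominance")[: len(terms)],
                            }
                        )
                        runs[coding] = evalcv.run_cv(
                            y_hyb, terms, c_spec, plan, target="hybrid_blue", coding=coding
                        )
                        acc_rows.append(
                            {
                                "target": "hybrid_blue",
                                "trait": trait,
                                "method": spec.method,
                                "coding": coding,
                                "accuracy": runs[coding].accuracy,
                                "sd": runs[coding].accuracy_sd,
                            }
                        )
                    if {"A", "AD"} <= set(runs):
                        cmp = evalcv.compare_runs(runs["A"], runs["AD"])
                        acc_rows.append(
                            {
                                "target": "hybrid_blue",
                                "trait": trait,
                                "method": spec.method,
                                "coding": "AD_vs_A_pct",
                                "accuracy": cmp.percent_change,
                                "sd": float("nan"),
                            }
                        )
        acc_df = pd.DataFrame(acc_rows)
        paths["accuracy"] = out / "accuracy.tsv"
        acc_df.to_csv(paths["accuracy"], sep="\t", index=False, float_format="%.6g")

        # ------------------------------------------------ report + manifest
        stage = "report"
        summary = {
            "filter": filter_report,
            "marker_stats_overall": {
                k: round(float(v), 6) for k, v in stats.overall.items()
            },
            "combining_ability": combine_df.round(6).to_dict(orient="records"),
            "accuracy": acc_df.round(6).to_dict(orient="records"),
        }
        paths["summary"] = out / "summary.json"
        paths["summary"].write_text(json.dumps(summary, indent=1, allow_nan=True))
        manifest = {
            "seed": config.seed,
            "stage_seeds": seeds,
            "inputs": {k: _digest(Path(v)) for k, v in inputs.items()},
            "n_markers_kept": filter_report["n_kept"],
            "models": [m.method for m in config.models],
            "cv": {"n_folds": config.cv.n_folds, "n_repeats": config.cv.n_repeats},
        }
        paths["manifest"] = out / "manifest.json"
        paths["manifest"].write_text(json.dumps(manifest, indent=1))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return paths
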