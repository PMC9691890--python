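"""Synthetic NC-II breeding experiments with known truth.

Generates fully inbred parental panels drawn from diverged subpopulations
(hierarchical Balding–Nichols-style allele frequencies), a line × tester
mating design, and multi-environment replicated hybrid phenotypes controlled
by additive + dominance QTL, with the realized GCA/SCA decomposition and
variance components recorded as ground truth.

The generator emulates the structure of real maize NC-II experiments
(hundreds of inbred lines crossed to a handful of testers, two environments
with two replicates each); it does not simulate linkage, recombination or
selection — markers are exchangeable within chromosomes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .combability import VarianceComponents
from .core import MISSING, GenotypeMatrix, MatingDesign, PhenotypeTable

# relative scale of fixed environment / replicate effects (in units of the
# genotypic SD); real trials show clear environment effects of this order
ENV_EFFECT_SCALE = 0.5
REP_EFFECT_SCALE = 0.1


@dataclass
class SimConfig:
    """Parameters of one synthetic NC-II experiment.

    Defaults mirror a mid-sized breeding population: 120 lines × 4 testers
    genotyped at 1000 SNPs across 10 chromosomes, 3 subpopulations with
    moderate divergence, a trait with 50 QTL, and 2 environments × 2
    replicates.
    """

    n_lines: int = 120
    n_testers: int = 4
    n_markers: int = 1000
    n_chromosomes: int = 10
    n_subpops: int = 3
    fst: float = 0.15
    n_qtl: int = 50
    dominance_ratio: float = 0.5
    h2_entry: float = 0.7
    n_envs: int = 2
    n_reps: int = 2
    gxe_ratio: float = 0.2
    residual_het_rate: float = 0.005
    missing_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        counts = dict(
            n_lines=self.n_lines,
            n_testers=self.n_testers,
            n_markers=self.n_markers,
            n_chromosomes=self.n_chromosomes,
            n_subpops=self.n_subpops,
            n_qtl=self.n_qtl,
            n_envs=self.n_envs,
            n_reps=self.n_reps,
        )
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_qtl > self.n_markers:
            raise ValueError("n_qtl cannot exceed n_markers")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must lie in [0, 1)")
        if not 0.0 < self.h2_entry <= 1.0:
            raise ValueError("h2_entry must lie in (0, 1]")
        if self.dominance_ratio < 0 or self.gxe_ratio < 0:
            raise ValueError("variance ratios must be >= 0")
        for name in ("residual_het_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class TruthSet:
    """Ground truth of a simulated experiment.

    GCA effects are centered; ``mu + gca_line + gca_tester + sca`` rebuilds
    each hybrid's genotypic value exactly.
    """

    qtl_indices: np.ndarray
    additive_effects: np.ndarray
    dominance_effects: np.ndarray
    mu: float
    genotypic_values: pd.Series
    true_gca_lines: pd.Series
    true_gca_testers: pd.Series
    true_sca: pd.Series
    true_components: VarianceComponents
    subpop_of: dict[str, int] = field(default_factory=dict)


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Split one seed into independent stage generators."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_founders(config: SimConfig) -> GenotypeMatrix:
    """Draw inbred parental genotypes from diverged subpopulations.

    Ancestral allele frequencies are uniform(0.1, 0.9); each subpopulation's
    frequency is Beta-distributed around the ancestral value with dispersion
    governed by ``fst`` (at fst=0 all subpopulations share the ancestral
    frequencies).  Samples are inbred: homozygous except residual
    heterozygous calls at ``residual_het_rate``; missing calls are inserted
    at ``missing_rate``.
    """
    cfg = config
    if cfg.n_markers < cfg.n_chromosomes:
        raise ValueError("need at least one marker per chromosome")
    rng_freq, rng_geno, rng_het, rng_miss = _rngs(cfg.seed, 4)

    m = cfg.n_markers
    p_anc = rng_freq.uniform(0.1, 0.9, size=m)
    if cfg.fst > 0:
        c = (1.0 - cfg.fst) / cfg.fst
        sub_freq = rng_freq.beta(
            p_anc * c, (1.0 - p_anc) * c, size=(cfg.n_subpops, m)
        )
    else:
        sub_freq = np.tile(p_anc, (cfg.n_subpops, 1))

    n = cfg.n_lines + cfg.n_testers
    sample_ids = [f"L{i + 1:03d}" for i in range(cfg.n_lines)] + [
        f"T{j + 1:02d}" for j in range(cfg.n_testers)
    ]
    subpop = np.arange(n) % cfg.n_subpops

    # inbred: a single allele draw per sample × marker, doubled
    dosage = 2 * (rng_geno.random((n, m)) < sub_freq[subpop]).astype(np.int8)
    if cfg.residual_het_rate > 0:
        het = rng_het.random((n, m)) < cfg.residual_het_rate
        dosage[het] = 1
    if cfg.missing_rate > 0:
        miss = rng_miss.random((n, m)) < cfg.missing_rate
        dosage[miss] = MISSING

    per_chrom = np.array_split(np.arange(m), cfg.n_chromosomes)
    chroms, positions = [], []
    for c_idx, block in enumerate(per_chrom, start=1):
        chroms += [f"chr{c_idx}"] * len(block)
        positions += list(1000 * (np.arange(len(block)) + 1))
    markers = pd.DataFrame(
        {
            "id": [f"snp{i + 1:05d}" for i in range(m)],
            "chrom": chroms,
            "pos": positions,
            "ref": ["A"] * m,
            "alt": ["G"] * m,
        }
    )
    g = GenotypeMatrix(sample_ids=sample_ids, markers=markers, dosage=dosage)
    g.subpop_of = dict(zip(sample_ids, subpop.tolist()))  # type: ignore[attr-defined]
    return g


def make_design(
    n_lines: int,
    n_testers: int,
    complete: bool = True,
    *,
    drop_fraction: float = 0.06,
    n_drop: int | None = None,
    seed: int = 0,
) -> MatingDesign:
    """Build the NC-II line × tester cross set.

    ``complete=True`` yields every cross; otherwise a random fraction
    (``drop_fraction``, or exactly ``n_drop`` crosses) is omitted, as happens
    in real programs where some F1 seed fails.
    """
    if n_lines < 1 or n_testers < 1:
        raise ValueError("counts must be >= 1")
    lines = [f"L{i + 1:03d}" for i in range(n_lines)]
    testers = [f"T{j + 1:02d}" for j in range(n_testers)]
    rows = [
        {"line": li, "tester": tj, "hybrid": f"{li}x{tj}"}
        for li in lines
        for tj in testers
    ]
    df = pd.DataFrame(rows)
    if not complete:
        k = n_drop if n_drop is not None else int(round(drop_fraction * len(df)))
        k = min(k, len(df) - 1)
        rng = np.random.default_rng(seed)
        drop = rng.choice(len(df), size=k, replace=False)
        df = df.drop(index=drop).reset_index(drop=True)
    return MatingDesign(table=df)


def _expected_f1(founders: GenotypeMatrix, design: MatingDesign):
    """Expected-F1 additive and dominance predictors at every marker.

    Each parent transmits its alt allele with probability dosage/2, so
    E[F1 dosage] = (a + b)/2 and P(F1 het) = (a/2)(1-b/2) + (b/2)(1-a/2).
    Missing parental calls are replaced by the marker's mean dosage
    (expected-dosage fill) for the purpose of defining genotypic truth.
    """
    d = founders.dosage.astype(float)
    d[founders.dosage == MISSING] = np.nan
    col_mean = np.nanmean(d, axis=0)
    if np.isnan(col_mean).any():
        col_mean = np.nan_to_num(col_mean, nan=1.0)
    filled = np.where(np.isnan(d), col_mean[None, :], d)

    li = founders.sample_index(list(design.table["line"]))
    ti = founders.sample_index(list(design.table["tester"]))
    a, b = filled[li] / 2.0, filled[ti] / 2.0
    x_add = a + b - 1.0  # E[F1 dosage] - 1 in [-1, 1]
    x_dom = a * (1.0 - b) + b * (1.0 - a)  # P(F1 heterozygous)
    return x_add, x_dom


def simulate_phenotypes(
    founders: GenotypeMatrix, design: MatingDesign, config: SimConfig
) -> tuple[PhenotypeTable, TruthSet]:
    """Simulate multi-environment replicated hybrid phenotypes.

    Hybrid genotypic values are sums of additive and dominance QTL
    contributions on the expected-F1 scale; dominance effects are rescaled so
    the realized dominance/additive variance ratio matches
    ``config.dominance_ratio``.  Residual noise is scaled so the realized
    entry-mean heritability matches ``config.h2_entry`` given the G×E level.
    """
    cfg = config
    missing_parents = (set(design.table["line"]) | set(design.table["tester"])) - set(
        founders.sample_ids
    )
    if missing_parents:
        raise KeyError(f"design parents absent from founders: {sorted(missing_parents)[:5]}")
    rng_qtl, rng_eff, rng_env, rng_gxe, rng_eps = _rngs(cfg.seed + 1, 5)

    qtl = np.sort(rng_qtl.choice(cfg.n_markers, size=cfg.n_qtl, replace=False))
    a_eff = rng_eff.normal(0.0, 1.0, size=cfg.n_qtl)
    d_raw = rng_eff.normal(0.0, 1.0, size=cfg.n_qtl)

    x_add, x_dom = _expected_f1(founders, design)
    g_add = x_add[:, qtl] @ a_eff
    var_add = float(np.var(g_add))
    if var_add <= 0 and cfg.h2_entry > 0:
        raise ValueError("additive genotypic variance is zero: heritability target unreachable")

    if cfg.dominance_ratio > 0:
        g_dom_raw = x_dom[:, qtl] @ d_raw
        var_dom_raw = float(np.var(g_dom_raw))
        if var_dom_raw <= 0:
            raise ValueError("dominance variance requested but no segregating heterozygosity")
        scale = np.sqrt(cfg.dominance_ratio * var_add / var_dom_raw)
        d_eff = d_raw * scale
        g_dom = g_dom_raw * scale
    else:
        d_eff = np.zeros(cfg.n_qtl)
        g_dom = np.zeros(len(design.table))

    g_val = g_add + g_dom
    hybrids = list(design.table["hybrid"])
    gv = pd.Series(g_val, index=hybrids)
    mu = float(gv.mean())

    line_of = design.table.set_index("hybrid")["line"]
    tester_of = design.table.set_index("hybrid")["tester"]
    gca_l = gv.groupby(line_of).mean() - mu
    gca_t = gv.groupby(tester_of).mean() - mu
    sca = gv - mu - gca_l.loc[line_of].to_numpy() - gca_t.loc[tester_of].to_numpy()

    var_g = float(gv.var(ddof=0))
    sigma_g = np.sqrt(var_g)
    var_ge = cfg.gxe_ratio * var_g
    e, r = cfg.n_envs, cfg.n_reps
    # residual scaled to hit the target entry-mean heritability
    var_eps = e * r * (var_g / cfg.h2_entry - var_g - var_ge / e)
    if var_eps < -1e-9 * max(var_g, 1.0):
        raise ValueError(
            "h2_entry target unreachable: G×E variance alone exceeds the "
            "allowed non-genetic share"
        )
    var_eps = max(var_eps, 0.0)

    env_eff = rng_env.normal(0.0, ENV_EFFECT_SCALE * sigma_g, size=e)
    rep_eff = rng_env.normal(0.0, REP_EFFECT_SCALE * sigma_g, size=(e, r))
    gxe = (
        rng_gxe.normal(0.0, np.sqrt(var_ge), size=(len(hybrids), e))
        if var_ge > 0
        else np.zeros((len(hybrids), e))
    )

    records = []
    for k in range(e):
        for m_ in range(r):
            eps = (
                rng_eps.normal(0.0, np.sqrt(var_eps), size=len(hybrids))
                if var_eps > 0
                else np.zeros(len(hybrids))
            )
            y = g_val + env_eff[k] + rep_eff[k, m_] + gxe[:, k] + eps
            records.append(
                pd.DataFrame(
                    {
                        "hybrid": hybrids,
                        "env": f"E{k + 1}",
                        "rep": m_ + 1,
                        "trait": y,
                    }
                )
            )
    pheno = PhenotypeTable(data=pd.concat(records, ignore_index=True))

    components = VarianceComponents(
        sigma2_gca_l=float(gca_l.var(ddof=0)),
        sigma2_gca_t=float(gca_t.var(ddof=0)),
        sigma2_sca=float(sca.var(ddof=0)),
        sigma2_gca_l_x_e=0.0,
        sigma2_gca_t_x_e=0.0,
        sigma2_sca_x_e=float(var_ge),
        sigma2_eps=float(var_eps),
        t=cfg.n_testers,
        r=r,
        e=e,
    )
    subpop = getattr(founders, "subpop_of", {})
    truth = TruthSet(
        qtl_indices=qtl,
        additive_effects=a_eff,
        dominance_effects=d_eff,
        mu=mu,
        genotypic_values=gv,
        true_gca_lines=gca_l,
        true_gca_testers=gca_t,
        true_sca=sca,
        true_components=components,
        subpop_of=subpop,
    )
    return pheno, truth


def simulate_from_components(
    components: VarianceComponents,
    *,
    n_lines: int,
    n_testers: int | None = None,
    seed: int = 0,
    mu: float = 100.0,
) -> tuple[PhenotypeTable, MatingDesign]:
    """Simulate a balanced complete NC-II trial directly from the mixed model.

    All random terms (GCA, SCA and their environment interactions, residual)
    are drawn as independent normals with the requested variances — the exact
    generative model of the combining-ability analysis, useful for parameter-
    recovery studies where QTL-level structure is not wanted.  ``t``, ``r``
    and ``e`` are taken from ``components`` (``n_testers`` may override
    ``t``).
    """
    t = n_testers if n_testers is not None else components.t
    e, r = components.e, components.r
    rng = np.random.default_rng(seed)
    design = make_design(n_lines, t, complete=True)
    li, ti = pd.factorize(design.table["line"])[0], pd.factorize(design.table["tester"])[0]
    gl = rng.normal(0, np.sqrt(components.sigma2_gca_l), n_lines)
    gt = rng.normal(0, np.sqrt(components.sigma2_gca_t), t)
    sc = rng.normal(0, np.sqrt(components.sigma2_sca), design.n_hybrids)
    gle = rng.normal(0, np.sqrt(components.sigma2_gca_l_x_e), (n_lines, e))
    gte = rng.normal(0, np.sqrt(components.sigma2_gca_t_x_e), (t, e))
    sce = rng.normal(0, np.sqrt(components.sigma2_sca_x_e), (design.n_hybrids, e))
    env_eff = rng.normal(0, 1.0, e)
    rep_eff = rng.normal(0, 0.25, (e, r))
    records = []
    for k in range(e):
        base = mu + env_eff[k] + gl[li] + gt[ti] + sc + gle[li, k] + gte[ti, k] + sce[:, k]
        for m_ in range(r):
            y = base + rep_eff[k, m_] + rng.normal(
                0, np.sqrt(components.sigma2_eps), design.n_hybrids
            )
            records.append(
                pd.DataFrame(
                    {
                        "hybrid": design.table["hybrid"],
                        "env": f"E{k + 1}",
                        "rep": m_ + 1,
                        "trait": y,
                    }
                )
            )
    return PhenotypeTable(data=pd.concat(records, ignore_index=True)), design


def write_simulation(
    founders: GenotypeMatrix,
    design: MatingDesign,
    pheno: PhenotypeTable,
    truth: TruthSet,
    directory: str | Path,
    *,
    overwrite: bool = False,
    with_dp_gq: bool = False,
) -> dict[str, Path]:
    """Write a simulated experiment to disk (VCF + TSV + JSON truth ledger)."""
    from . import genio

    if design.n_hybrids == 0:
        raise ValueError("empty mating design")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": directory / "parents.vcf",
        "mating": directory / "mating.tsv",
        "phenotypes": directory / "phenotypes.tsv",
        "truth": directory / "truth.json",
    }
    clashes = [p for p in paths.values() if p.exists()]
    if clashes and not overwrite:
        raise FileExistsError(f"refusing to overwrite {clashes[0]} (pass overwrite=True)")

    genio.write_vcf(founders, paths["vcf"], with_dp_gq=with_dp_gq)
    design.table.to_csv(paths["mating"], sep="\t", index=False)
    pheno.data.to_csv(paths["phenotypes"], sep="\t", index=False)

    ledger = {
        "qtl_indices": truth.qtl_indices.tolist(),
        "additive_effects": truth.additive_effects.tolist(),
        "dominance_effects": truth.dominance_effects.tolist(),
        "mu": truth.mu,
        "genotypic_values": truth.genotypic_values.to_dict(),
        "true_gca_lines": truth.true_gca_lines.to_dict(),
        "true_gca_testers": truth.true_gca_testers.to_dict(),
        "true_sca": truth.true_sca.to_dict(),
        "true_components": truth.true_components.as_dict()
        | {
            "t": truth.true_components.t,
            "r": truth.true_components.r,
            "e": truth.true_components.e,
        },
        "subpop_of": truth.subpop_of,
    }
    paths["truth"].write_text(json.dumps(ledger, indent=1))
    return paths


def read_truth(path: str | Path) -> TruthSet:
    """Re-read a truth ledger written by :func:`write_simulation`."""
    raw = json.loads(Path(path).read_text())
    comp = raw["true_components"]
    return TruthSet(
        qtl_indices=np.asarray(raw["qtl_indices"], dtype=int),
        additive_effects=np.asarray(raw["additive_effects"], dtype=float),
        dominance_effects=np.asarray(raw["dominance_effects"], dtype=float),
        mu=float(raw["mu"]),
        genotypic_values=pd.Series(raw["genotypic_values"]),
        true_gca_lines=pd.Series(raw["true_gca_lines"]),
        true_gca_testers=pd.Series(raw["true_gca_testers"]),
        true_sca=pd.Series(raw["true_sca"]),
        true_components=VarianceComponents(
            **{k: comp[k] for k in comp if k.startswith("sigma2")},
            t=comp["t"],
            r=comp["r"],
            e=comp["e"],
        ),
        subpop_of={k: int(v) for k, v in raw.get("subpop_of", {}).items()},
    )
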