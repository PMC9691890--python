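"""Cross-validation engine and accuracy bookkeeping.

Prediction accuracy is estimated by repeated k-fold cross-validation: per
repeat a seeded random partition into folds of near-equal size, per fold a
fit on the training rows and a Pearson correlation between predictions and
the observed response on the test rows; the summary accuracy is the grand
mean over folds and repeats (the pooled-across-folds correlation per repeat
is reported alongside).

The same engine serves both targets: line GCA (response = mixed-model GCA
estimates, predictors = parental −1/0/1 codes) and hybrid performance
(response = entry-mean BLUEs, predictors = hybrid A and D codes).  Marker
subset experiments (functional vs same-count random subsets) and
cross-panel marker intersection live here too.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gsmodels
from .core import GenotypeMatrix
from .gsmodels import ModelSpec

logger = logging.getLogger(__name__)


@dataclass
class CVPlan:
    """Repeated k-fold cross-validation layout."""

    n_folds: int = 10
    n_repeats: int = 100
    seed: int = 0
    stratify: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")
        if self.n_repeats < 1:
            raise ValueError("need at least 1 repeat")

    def partitions(self, n: int):
        """Yield (repeat, fold, test_index) with deterministic seeding.

        Every row lands in exactly one test fold per repeat and fold sizes
        differ by at most one.  With ``stratify`` set, rows are dealt to
        folds within each stratum.
        """
        if n < 2 * self.n_folds:
            raise ValueError(f"need at least {2 * self.n_folds} rows for {self.n_folds}-fold CV")
        rng = np.random.default_rng(self.seed)
        for rep in range(self.n_repeats):
            fold_of = np.empty(n, dtype=int)
            if self.stratify is None:
                perm = rng.permutation(n)
                fold_of[perm] = np.arange(n) % self.n_folds
            else:
                strata = np.asarray(self.stratify)
                offset = 0
                for s in pd.unique(strata):
                    idx = np.flatnonzero(strata == s)
                    perm = rng.permutation(idx)
                    fold_of[perm] = (np.arange(idx.size) + offset) % self.n_folds
                    offset += idx.size
            # partition validity: disjoint and exhaustive by construction,
            # asserted anyway per the engine's contract
            assert np.bincount(fold_of, minlength=self.n_folds).min() >= 1
            for fold in range(self.n_folds):
                yield rep, fold, np.flatnonzero(fold_of == fold)


@dataclass
class PredictionRun:
    """Per-fold accuracies and their summary for one model/coding/target."""

    spec: ModelSpec
    target: str  # gca_line | hybrid_blue
    coding: str  # A | AD | parental
    records: pd.DataFrame  # repeat, fold, n_test, r
    pooled_by_repeat: pd.Series
    n_undefined: int = 0

    @property
    def accuracy(self) -> float:
        """Grand mean test-set correlation over folds and repeats."""
        return float(self.records["r"].mean())

    @property
    def accuracy_sd(self) -> float:
        return float(self.records["r"].std(ddof=1))


def run_cv(
    y,
    X_terms,
    spec: ModelSpec,
    plan: CVPlan,
    *,
    target: str = "hybrid_blue",
    coding: str = "A",
) -> PredictionRun:
    """Repeated k-fold cross-validated accuracy of one model.

    Folds with a constant observed test response have an undefined
    correlation; they are recorded as missing, excluded from the mean, and
    counted in ``n_undefined``.
    """
    y = np.asarray(y, dtype=float).ravel()
    terms = [np.asarray(t.values if hasattr(t, "values") else t, dtype=float) for t in X_terms]
    n = y.shape[0]
    rows = []
    pooled: dict[int, list] = {}
    n_undef = 0
    for rep, fold, test_idx in plan.partitions(n):
        train = np.ones(n, dtype=bool)
        train[test_idx] = False
        fold_spec = ModelSpec(
            **{
                **spec.__dict__,
                "seed": (spec.seed + 7919 * rep + 104729 * fold) % 2**31,
            }
        )
        fm = gsmodels.fit(y[train], [Z[train] for Z in terms], fold_spec)
        pred = gsmodels.predict(fm, [Z[test_idx] for Z in terms])
        obs = y[test_idx]
        if np.std(obs) == 0 or np.std(pred) == 0:
            r = np.nan
            n_undef += 1
        else:
            r = float(np.corrcoef(pred, obs)[0, 1])
        rows.append({"repeat": rep, "fold": fold, "n_test": test_idx.size, "r": r})
        pooled.setdefault(rep, []).append((pred, obs))
    if n_undef:
        logger.info("%d folds with undefined correlation excluded", n_undef)
    records = pd.DataFrame(rows)
    pooled_r = {}
    for rep, pairs in pooled.items():
        p = np.concatenate([a for a, _ in pairs])
        o = np.concatenate([b for _, b in pairs])
        pooled_r[rep] = float(np.corrcoef(p, o)[0, 1]) if np.std(o) > 0 else np.nan
    return PredictionRun(
        spec=spec,
        target=target,
        coding=coding,
        records=records,
        pooled_by_repeat=pd.Series(pooled_r),
        n_undefined=n_undef,
    )


@dataclass
class RunComparison:
    percent_change: float
    delta: float
    paired_fold_diffs: pd.Series
    undefined: bool = False


def compare_runs(a: PredictionRun, b: PredictionRun) -> RunComparison:
    """Relative accuracy change 100·(acc_b − acc_a)/acc_a, with paired
    per-fold differences where the two runs share a CV layout."""
    if a.target != b.target:
        raise ValueError("runs have different targets")
    if len(a.records) != len(b.records):
        raise ValueError("runs have different CV plans")
    acc_a, acc_b = a.accuracy, b.accuracy
    diffs = b.records["r"] - a.records["r"]
    if acc_a == 0:
        return RunComparison(float("nan"), acc_b - acc_a, diffs, undefined=True)
    return RunComparison(100.0 * (acc_b - acc_a) / acc_a, acc_b - acc_a, diffs)


def intersect_markers(g1: GenotypeMatrix, g2: GenotypeMatrix) -> pd.DataFrame:
    """Markers shared between two panels, matched on (chrom, pos, ref, alt).

    Allele-swapped records (ref/alt exchanged between panels) are matched
    with ``flipped=True``; downstream codes built from the second panel must
    be sign-flipped at those markers.  Returns a frame with the ids in both
    panels and the flip flag; empty (with a warning) if nothing is shared.
    """
    m1 = g1.markers.rename(columns={"id": "id_1"})
    m2 = g2.markers.rename(columns={"id": "id_2"})
    direct = m1.merge(m2, on=["chrom", "pos", "ref", "alt"])[["id_1", "id_2", "chrom", "pos"]]
    direct["flipped"] = False
    m2_sw = m2.rename(columns={"ref": "alt", "alt": "ref"})
    swapped = m1.merge(m2_sw, on=["chrom", "pos", "ref", "alt"])[["id_1", "id_2", "chrom", "pos"]]
    swapped["flipped"] = True
    out = (
        pd.concat([direct, swapped], ignore_index=True)
        .drop_duplicates(subset=["chrom", "pos"])
        .sort_values(["chrom", "pos"])
        .reset_index(drop=True)
    )
    if out.empty:
        logger.warning("no markers shared between the two panels")
    return out


@dataclass
class SubsetExperiment:
    functional: PredictionRun
    random: PredictionRun
    random_marker_ids: list = field(default_factory=list)


def subset_experiment(
    y,
    coded,
    markers_functional: list[str],
    markers_pool: list[str],
    k: int,
    spec: ModelSpec,
    plan: CVPlan,
    *,
    seed: int = 0,
    target: str = "hybrid_blue",
) -> SubsetExperiment:
    """Paired CV runs: a functional marker subset vs a same-size random draw
    from the non-functional pool.

    ``coded`` is a CodedMatrix (or list of them for AD) covering all markers;
    columns are selected by id.  The functional and pool sets must not
    overlap.
    """
    overlap = set(markers_functional) & set(markers_pool)
    if overlap:
        raise ValueError(f"functional set overlaps pool: {sorted(overlap)[:5]}")
    if k > len(markers_pool):
        raise ValueError("k exceeds the size of the random pool")
    coded_list = coded if isinstance(coded, (list, tuple)) else [coded]
    rng = np.random.default_rng(seed)
    random_ids = list(rng.choice(np.asarray(markers_pool, dtype=object), size=k, replace=False))

    def take(ids):
        out = []
        for cm in coded_list:
            pos = [cm.marker_ids.index(i) for i in ids]
            out.append(cm.values[:, pos])
        return out

    run_f = run_cv(y, take(markers_functional), spec, plan, target=target, coding="functional")
    run_r = run_cv(y, take(random_ids), spec, plan, target=target, coding="random")
    return SubsetExperiment(functional=run_f, random=run_r, random_marker_ids=random_ids)
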