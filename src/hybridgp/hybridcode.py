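"""Predictor codings for genomic prediction.

Three codings are produced from parental dosage genotypes:

* ``parental_additive`` — the −1/0/1 coding of each parent's own genotype
  (hom-ref −1, het 0, hom-alt +1), used to predict line GCA;
* ``hybrid_additive`` — the expected-F1 additive code: for parents with
  dosages (a, b) it equals E[F1 alt dosage] − 1 = (a + b)/2 − 1, which
  reproduces the rule set −1/0/+1 for hom × hom matings, ∓0.5 for
  hom × het matings and 0 for het × het;
* ``hybrid_dominance`` — the probability that the F1 is heterozygous:
  0 for identical-homozygote matings, 1 for opposite homozygotes, 0.5
  whenever a heterozygous parent is involved.

Missing parental calls are imputed first by randomized draws from each
marker's observed genotype-class frequencies, so coded matrices contain no
missing values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, MatingDesign


@dataclass
class CodedMatrix:
    """A fully observed real-valued predictor matrix (rows × markers)."""

    row_ids: list[str]
    marker_ids: list[str]
    values: np.ndarray
    coding_kind: str  # parental_additive | hybrid_additive | hybrid_dominance

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.marker_ids)):
            raise ValueError("values shape does not match row/marker ids")
        if np.isnan(self.values).any():
            raise ValueError("coded matrices must not contain missing values")
        allowed = {
            "parental_additive": {-1.0, 0.0, 1.0},
            "hybrid_additive": {-1.0, -0.5, 0.0, 0.5, 1.0},
            "hybrid_dominance": {0.0, 0.5, 1.0},
        }
        if self.coding_kind not in allowed:
            raise ValueError(f"unknown coding kind {self.coding_kind!r}")
        if not set(np.unique(self.values)) <= allowed[self.coding_kind]:
            raise ValueError(f"illegal values for coding {self.coding_kind!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.marker_ids)


def impute_dosage(g: GenotypeMatrix, seed: int) -> np.ndarray:
    """Randomized imputation from observed genotype-class frequencies.

    Each missing cell is drawn from {0, 1, 2} with the marker's observed
    class frequencies, using its own deterministic stream derived from
    ``seed``.  A marker with no observed calls cannot be imputed.
    """
    rng = np.random.default_rng(seed)
    dosage = g.dosage.astype(np.int8).copy()
    miss = g.missing_mask
    if not miss.any():
        return dosage
    for j in np.flatnonzero(miss.any(axis=0)):
        obs = dosage[~miss[:, j], j]
        if obs.size == 0:
            raise ValueError(
                f"marker {g.markers['id'].iloc[j]!r} has no observed calls; cannot impute"
            )
        freqs = np.bincount(obs, minlength=3) / obs.size
        n_miss = int(miss[:, j].sum())
        dosage[miss[:, j], j] = rng.choice(3, size=n_miss, p=freqs).astype(np.int8)
    return dosage


def code_parents(g: GenotypeMatrix, seed: int = 0) -> CodedMatrix:
    """−1/0/1 coding of parental genotypes with randomized imputation."""
    dosage = impute_dosage(g, seed)
    return CodedMatrix(
        row_ids=list(g.sample_ids),
        marker_ids=list(g.markers["id"]),
        values=dosage.astype(float) - 1.0,
        coding_kind="parental_additive",
    )


def f1_codes(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Additive and dominance codes of the expected F1 of parental dosages.

    ``A = E[F1 dosage] − 1`` and ``D = P(F1 heterozygous)``; each parent
    transmits its alternate allele with probability dosage/2.
    """
    pa, pb = a / 2.0, b / 2.0
    return pa + pb - 1.0, pa * (1.0 - pb) + pb * (1.0 - pa)


def code_hybrids(
    g: GenotypeMatrix, design: MatingDesign, seed: int = 0
) -> tuple[CodedMatrix, CodedMatrix]:
    """Additive (A) and dominance (D) hybrid codings from parental genotypes.

    Parental missing cells are imputed first (same randomized scheme as
    :func:`code_parents`); the F1 codes then follow deterministically from
    the two parental dosages.
    """
    unknown = (set(design.table["line"]) | set(design.table["tester"])) - set(g.sample_ids)
    if unknown:
        raise KeyError(f"unknown parent ids in design: {sorted(unknown)[:5]}")
    dosage = impute_dosage(g, seed).astype(float)
    li = g.sample_index(list(design.table["line"]))
    ti = g.sample_index(list(design.table["tester"]))
    add, dom = f1_codes(dosage[li], dosage[ti])
    hybrids = list(design.table["hybrid"])
    marker_ids = list(g.markers["id"])
    return (
        CodedMatrix(hybrids, marker_ids, add, "hybrid_additive"),
        CodedMatrix(hybrids, marker_ids, dom, "hybrid_dominance"),
    )


def write_coded(coded: CodedMatrix, path) -> None:
    coded.to_frame().to_csv(path, sep="\t", index_label="row")
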