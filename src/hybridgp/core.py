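"""Core data containers shared across the pipeline.

The pipeline revolves around three objects: a :class:`GenotypeMatrix` holding
parental SNP dosages, a :class:`MatingDesign` describing which line × tester
crosses exist, and a :class:`PhenotypeTable` with multi-environment replicated
hybrid trait records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: sentinel for a missing genotype call in dosage matrices
MISSING = -1

MARKER_COLUMNS = ["id", "chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Samples × biallelic markers, coded as alt-allele dosage {0, 1, 2}.

    Missing calls are stored as :data:`MISSING` (-1).  ``markers`` is a frame
    with columns ``id, chrom, pos, ref, alt``; positions are 1-based and
    strictly increasing within a chromosome.  Optional per-call read depth
    (``dp``) and genotype quality (``gq``) arrays support quality masking.
    """

    sample_ids: list[str]
    markers: pd.DataFrame
    dosage: np.ndarray
    dp: np.ndarray | None = None
    gq: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.sample_ids), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples × {len(self.markers)} markers"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicated sample ids")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage codes must be in {0, 1, 2, missing}")
        self.markers = self.markers.reset_index(drop=True)
        for chrom, grp in self.markers.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def sample_index(self, ids: list[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from None

    def take_samples(self, ids: list[str]) -> "GenotypeMatrix":
        idx = self.sample_index(ids)
        return GenotypeMatrix(
            sample_ids=list(ids),
            markers=self.markers.copy(),
            dosage=self.dosage[idx],
            dp=None if self.dp is None else self.dp[idx],
            gq=None if self.gq is None else self.gq[idx],
        )

    def take_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            markers=self.markers.iloc[index].reset_index(drop=True),
            dosage=self.dosage[:, index],
            dp=None if self.dp is None else self.dp[:, index],
            gq=None if self.gq is None else self.gq[:, index],
        )


@dataclass
class MatingDesign:
    """NC-II factorial design: the realized set of line × tester hybrids."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        required = {"line", "tester", "hybrid"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"mating table needs columns {sorted(required)}")
        if self.table["hybrid"].duplicated().any():
            raise ValueError("duplicated hybrid ids in mating table")
        self.table = self.table.reset_index(drop=True)

    @property
    def lines(self) -> list[str]:
        return list(pd.unique(self.table["line"]))

    @property
    def testers(self) -> list[str]:
        return list(pd.unique(self.table["tester"]))

    @property
    def hybrids(self) -> list[str]:
        return list(self.table["hybrid"])

    @property
    def n_hybrids(self) -> int:
        return len(self.table)

    def parents_of(self, hybrid: str) -> tuple[str, str]:
        row = self.table.loc[self.table["hybrid"] == hybrid]
        if row.empty:
            raise KeyError(f"unknown hybrid {hybrid!r}")
        return row.iloc[0]["line"], row.iloc[0]["tester"]


@dataclass
class PhenotypeTable:
    """Hybrid × environment × replicate trait observations (long format).

    ``data`` has columns ``hybrid, env, rep`` plus one numeric column per
    trait.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"hybrid", "env", "rep"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"phenotype table needs columns {sorted(required)}")
        self.data = self.data.reset_index(drop=True)

    @property
    def traits(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("hybrid", "env", "rep")]

    @property
    def envs(self) -> list[str]:
        return sorted(self.data["env"].astype(str).unique())

    def entry_means(self, trait: str) -> pd.Series:
        """Raw hybrid means across all environments and replicates."""
        if trait not in self.traits:
            raise KeyError(f"unknown trait {trait!r}")
        return self.data.groupby("hybrid")[trait].mean()
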