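"""VCF genotype input, quality filtering and marker diversity statistics.

Parental SNP panels are read from VCF into a dosage :class:`GenotypeMatrix`.
Filtering follows the usual targeted-genotyping pipeline: per-call masking at
read depth < 11 or genotype quality < 20, then marker removal at minor allele
frequency ≤ 0.05, missing rate > 10% or heterozygosity > 1% (the parents are
inbreds, so residual heterozygosity indicates a bad assay).

Diversity statistics per marker: minor allele frequency (MAF), gene diversity
GD = 1 − Σ p_i², and polymorphic information content
PIC = 1 − Σ p_i² − Σ_{i<j} 2 p_i² p_j², with allele frequencies estimated
from non-missing calls (a heterozygote contributes one copy of each allele).
For a biallelic marker PIC = GD − 2 p² q² and the attainable maxima are
GD = 0.5 and PIC = 0.375 at p = 0.5.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class FilterSpec:
    """Thresholds of the per-call and per-marker filters.

    ``max_maf_excl`` is an exclusive-keep threshold: markers with
    MAF ≤ the threshold are removed.
    """

    min_dp: int = 11
    min_gq: int = 20
    max_maf_excl: float = 0.05
    max_missing: float = 0.10
    max_het: float = 0.01

    def __post_init__(self) -> None:
        if self.min_dp < 0 or self.min_gq < 0:
            raise ValueError("quality thresholds must be non-negative")
        for name in ("max_maf_excl", "max_missing", "max_het"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class MarkerStats:
    """Per-marker diversity statistics plus per-chromosome and overall means."""

    table: pd.DataFrame  # marker, chrom, pos, maf, gd, pic, missing, het
    by_chromosome: pd.DataFrame
    overall: pd.Series


def read_vcf(path: str | Path, sample_subset: list[str] | None = None) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a dosage matrix.

    Non-biallelic or non-SNP records are skipped (count logged).  Per-call DP
    and GQ are retained when the FORMAT defines them, for later quality
    masking.  Missing genotypes become the explicit missing code.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    all_samples = list(vcf.samples)
    if len(set(all_samples)) != len(all_samples):
        raise ValueError("duplicated sample ids in VCF header")
    if sample_subset is not None:
        missing = set(sample_subset) - set(all_samples)
        if missing:
            raise KeyError(f"samples not in VCF: {sorted(missing)}")
        vcf.set_samples(sample_subset)
    samples = list(vcf.samples)

    rows, dos, dps, gqs = [], [], [], []
    n_skipped = 0
    has_dp = has_gq = False
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        gt = var.gt_types  # 0=hom-ref, 1=het, 2=hom-alt(=3 in cyvcf2), 3=unknown
        d = np.full(len(samples), MISSING, dtype=np.int8)
        d[gt == 0] = 0
        d[gt == 1] = 1
        d[gt == 3] = 2
        dos.append(d)
        rows.append(
            {
                "id": var.ID or f"{var.CHROM}_{var.POS}",
                "chrom": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alt": var.ALT[0],
            }
        )
        try:
            dp = var.format("DP")
        except KeyError:
            dp = None
        try:
            gq = var.format("GQ")
        except KeyError:
            gq = None
        if dp is not None:
            has_dp = True
            dps.append(np.asarray(dp, dtype=np.int32).ravel())
        else:
            dps.append(np.full(len(samples), -1, dtype=np.int32))
        if gq is not None:
            has_gq = True
            gqs.append(np.asarray(gq, dtype=np.int32).ravel())
        else:
            gqs.append(np.full(len(samples), -1, dtype=np.int32))
    if n_skipped:
        logger.info("skipped %d non-biallelic-SNP records", n_skipped)
    if not rows:
        raise ValueError(f"no biallelic SNP records in {path}")

    g = GenotypeMatrix(
        sample_ids=samples,
        markers=pd.DataFrame(rows),
        dosage=np.column_stack(dos),
        dp=np.column_stack(dps) if has_dp else None,
        gq=np.column_stack(gqs) if has_gq else None,
    )
    if sample_subset is not None:
        g = g.take_samples(sample_subset)  # enforce requested order
    g.n_skipped_records = n_skipped  # type: ignore[attr-defined]
    return g


def write_vcf(g: GenotypeMatrix, path: str | Path, *, with_dp_gq: bool = False) -> None:
    """Write a GenotypeMatrix as a minimal VCF 4.2 file (GT, optional DP/GQ)."""
    path = Path(path)
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    fmt = "GT:DP:GQ" if with_dp_gq else "GT"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(g.markers["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if with_dp_gq:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.sample_ids)
            + "\n"
        )
        for j, marker in g.markers.iterrows():
            calls = []
            for i in range(g.n_samples):
                c = gt_str[int(g.dosage[i, j])]
                if with_dp_gq:
                    dp = g.dp[i, j] if g.dp is not None else 99
                    gq = g.gq[i, j] if g.gq is not None else 99
                    c = f"{c}:{dp}:{gq}"
                calls.append(c)
            fh.write(
                f"{marker['chrom']}\t{marker['pos']}\t{marker['id']}\t"
                f"{marker['ref']}\t{marker['alt']}\t.\tPASS\t.\t{fmt}\t"
                + "\t".join(calls)
                + "\n"
            )


def mask_low_quality(g: GenotypeMatrix, spec: FilterSpec | None = None) -> GenotypeMatrix:
    """Set calls with DP < min_dp or GQ < min_gq to missing.

    A matrix without DP/GQ information is returned unchanged with a warning.
    """
    spec = spec or FilterSpec()
    if g.dp is None and g.gq is None:
        warnings.warn("no DP/GQ information present; quality masking skipped", stacklevel=2)
        return g
    dosage = g.dosage.copy()
    if g.dp is not None:
        dosage[(g.dp >= 0) & (g.dp < spec.min_dp)] = MISSING
    if g.gq is not None:
        dosage[(g.gq >= 0) & (g.gq < spec.min_gq)] = MISSING
    return GenotypeMatrix(
        sample_ids=list(g.sample_ids),
        markers=g.markers.copy(),
        dosage=dosage,
        dp=g.dp,
        gq=g.gq,
    )


def _per_marker_rates(g: GenotypeMatrix):
    miss = g.missing_mask
    n_nonmiss = (~miss).sum(axis=0)
    d = np.where(miss, 0, g.dosage).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_alt = d.sum(axis=0) / (2.0 * n_nonmiss)
        het = (g.dosage == 1).sum(axis=0) / n_nonmiss
    missing_rate = miss.mean(axis=0)
    return p_alt, het, missing_rate, n_nonmiss


def filter_markers(
    g: GenotypeMatrix, spec: FilterSpec | None = None
) -> tuple[GenotypeMatrix, dict]:
    """Remove markers failing the MAF / missing-rate / heterozygosity filters.

    Removal rules: MAF ≤ ``max_maf_excl``; missing rate > ``max_missing``;
    heterozygous-call rate > ``max_het``.  The report lists per-criterion and
    unique removal counts (one marker may fail several rules).  Idempotent.
    """
    spec = spec or FilterSpec()
    p_alt, het, missing_rate, n_nonmiss = _per_marker_rates(g)
    maf = np.minimum(p_alt, 1.0 - p_alt)
    fail_maf = (maf <= spec.max_maf_excl) | (n_nonmiss == 0)
    fail_missing = missing_rate > spec.max_missing
    fail_het = np.where(n_nonmiss > 0, het > spec.max_het, True)
    fail_any = fail_maf | fail_missing | fail_het
    report = {
        "n_input": g.n_markers,
        "removed_maf": int(fail_maf.sum()),
        "removed_missing": int(fail_missing.sum()),
        "removed_het": int(fail_het.sum()),
        "removed_unique": int(fail_any.sum()),
        "n_kept": int((~fail_any).sum()),
    }
    if report["n_kept"] == 0:
        dominant = max(
            ("MAF", report["removed_maf"]),
            ("missing rate", report["removed_missing"]),
            ("heterozygosity", report["removed_het"]),
            key=lambda kv: kv[1],
        )[0]
        raise ValueError(f"all markers removed; dominant criterion: {dominant}")
    return g.take_markers(~fail_any), report


def biallelic_pic(p: np.ndarray) -> np.ndarray:
    """PIC for a biallelic marker with alt frequency p."""
    q = 1.0 - p
    return 1.0 - (p**2 + q**2) - 2.0 * p**2 * q**2


def biallelic_gd(p: np.ndarray) -> np.ndarray:
    """Gene diversity (expected heterozygosity) 1 − Σ p_i² = 2pq."""
    q = 1.0 - p
    return 1.0 - (p**2 + q**2)


def marker_stats(g: GenotypeMatrix) -> MarkerStats:
    """Per-marker MAF, GD, PIC, missing rate, heterozygosity, plus means.

    Markers with no non-missing calls are NaN-flagged in every frequency-based
    column and excluded from the means.
    """
    p_alt, het, missing_rate, n_nonmiss = _per_marker_rates(g)
    empty = n_nonmiss == 0
    p = np.where(empty, np.nan, p_alt)
    table = pd.DataFrame(
        {
            "marker": g.markers["id"],
            "chrom": g.markers["chrom"],
            "pos": g.markers["pos"],
            "maf": np.minimum(p, 1.0 - p),
            "gd": biallelic_gd(p),
            "pic": biallelic_pic(p),
            "missing": missing_rate,
            "het": np.where(empty, np.nan, het),
        }
    )
    stat_cols = ["maf", "gd", "pic", "missing", "het"]
    by_chrom = table.groupby("chrom", sort=False)[stat_cols].mean()
    overall = table[stat_cols].mean()
    return MarkerStats(table=table, by_chromosome=by_chrom, overall=overall)


def write_stats(stats: MarkerStats, path: str | Path) -> None:
    """Write the per-marker table plus a per-chromosome summary block."""
    path = Path(path)
    with open(path, "w") as fh:
        stats.table.to_csv(fh, sep="\t", index=False, float_format="%.6g")
        fh.write("\n# per-chromosome means\n")
        stats.by_chromosome.to_csv(fh, sep="\t", float_format="%.6g")
        fh.write("\n# overall means\n")
        stats.overall.to_frame().T.to_csv(fh, sep="\t", index=False, float_format="%.6g")
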