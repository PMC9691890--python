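import numpy as np
import pandas as pd
import pytest

from hybridgp.core import GenotypeMatrix, MatingDesign


def make_genotypes(dosage, sample_ids=None, dp=None, gq=None, chrom=None):
    """Build a small GenotypeMatrix from a dosage array."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    if sample_ids is None:
        sample_ids = [f"s{i + 1}" for i in range(n)]
    chroms = chrom if chrom is not None else ["chr1"] * m
    markers = pd.DataFrame(
        {
            "id": [f"m{j + 1}" for j in range(m)],
            "chrom": chroms,
            "pos": _positions(chroms),
            "ref": ["A"] * m,
            "alt": ["G"] * m,
        }
    )
    return GenotypeMatrix(
        sample_ids=list(sample_ids),
        markers=markers,
        dosage=dosage,
        dp=None if dp is None else np.asarray(dp, dtype=np.int32),
        gq=None if gq is None else np.asarray(gq, dtype=np.int32),
    )


def _positions(chroms):
    pos, counter = [], {}
    for c in chroms:
        counter[c] = counter.get(c, 0) + 100
        pos.append(counter[c])
    return pos


@pytest.fixture
def toy_design():
    table = pd.DataFrame(
        {
            "line": ["L001", "L001", "L002", "L002"],
            "tester": ["T01", "T02", "T01", "T02"],
            "hybrid": ["L001xT01", "L001xT02", "L002xT01", "L002xT02"],
        }
    )
    return MatingDesign(table=table)


@pytest.fixture(scope="session")
def small_sim():
    """One small complete NC-II simulation shared across tests."""
    from hybridgp import simdata

    cfg = simdata.SimConfig(
        n_lines=40,
        n_testers=4,
        n_markers=300,
        n_qtl=30,
        dominance_ratio=0.5,
        h2_entry=0.7,
        gxe_ratio=0.2,
        missing_rate=0.01,
        seed=3,
    )
    founders = simdata.simulate_founders(cfg)
    design = simdata.make_design(cfg.n_lines, cfg.n_testers, complete=True)
    pheno, truth = simdata.simulate_phenotypes(founders, design, cfg)
    return cfg, founders, design, pheno, truth
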