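"""Generator sanity: determinism, structure, truth decomposition, round-trips."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hybridgp import simdata


def test_deterministic_under_seed():
    cfg = simdata.SimConfig(n_lines=20, n_testers=3, n_markers=100, n_qtl=10, seed=7)
    g1 = simdata.simulate_founders(cfg)
    g2 = simdata.simulate_founders(cfg)
    assert np.array_equal(g1.dosage, g2.dosage)
    des = simdata.make_design(20, 3)
    p1, t1 = simdata.simulate_phenotypes(g1, des, cfg)
    p2, t2 = simdata.simulate_phenotypes(g2, des, cfg)
    pd.testing.assert_frame_equal(p1.data, p2.data)
    assert np.array_equal(t1.qtl_indices, t2.qtl_indices)


def test_degenerate_parameters_give_uniform_pop_and_no_hets():
    cfg = simdata.SimConfig(
        n_lines=50, n_testers=2, n_markers=200, n_subpops=3,
        fst=0.0, residual_het_rate=0.0, missing_rate=0.0, seed=1,
    )
    g = simdata.simulate_founders(cfg)
    assert (g.dosage != 1).all()  # fully inbred
    assert not g.missing_mask.any()


def test_config_validation():
    with pytest.raises(ValueError):
        simdata.SimConfig(n_qtl=50, n_markers=10)
    with pytest.raises(ValueError):
        simdata.SimConfig(fst=1.0)
    with pytest.raises(ValueError):
        simdata.SimConfig(h2_entry=0.0)
    cfg = simdata.SimConfig(n_markers=5, n_chromosomes=10, n_qtl=2)
    with pytest.raises(ValueError):
        simdata.simulate_founders(cfg)


def test_subpop_divergence_orders_ibs_distances():
    from hybridgp import popstruct

    cfg = simdata.SimConfig(
        n_lines=200, n_testers=4, n_markers=2000, n_subpops=3,
        fst=0.2, missing_rate=0.0, seed=5,
    )
    g = simdata.simulate_founders(cfg)
    d = popstruct.ibs_distance(g).values
    sub = np.array([g.subpop_of[s] for s in g.sample_ids])
    same = sub[:, None] == sub[None, :]
    off = ~np.eye(len(sub), dtype=bool)
    assert d[same & off].mean() < d[~same].mean()


def test_ancestral_frequency_distribution_at_fst_zero():
    """With no divergence, estimated allele frequencies follow the ancestral
    uniform(0.1, 0.9) distribution (KS sanity at alpha=0.01)."""
    cfg = simdata.SimConfig(
        n_lines=400, n_testers=4, n_markers=1500, n_subpops=2,
        fst=0.0, missing_rate=0.0, residual_het_rate=0.0, seed=9,
    )
    g = simdata.simulate_founders(cfg)
    freq = g.dosage.mean(axis=0) / 2.0
    # estimated frequencies = uniform ancestral + binomial sampling noise;
    # compare against the uniform via a simulated reference sample
    rng = np.random.default_rng(0)
    p_ref = rng.uniform(0.1, 0.9, 20000)
    ref = rng.binomial(g.n_samples, p_ref) / g.n_samples
    assert sps.ks_2samp(freq, ref).pvalue > 0.01


def test_truth_decomposition_is_exact(small_sim):
    _, _, design, _, truth = small_sim
    line_of = design.table.set_index("hybrid")["line"]
    tester_of = design.table.set_index("hybrid")["tester"]
    recon = (
        truth.mu
        + truth.true_gca_lines.loc[line_of].to_numpy()
        + truth.true_gca_testers.loc[tester_of].to_numpy()
        + truth.true_sca.to_numpy()
    )
    np.testing.assert_allclose(recon, truth.genotypic_values.to_numpy(), atol=1e-10)
    assert abs(truth.true_gca_lines.sum()) < 1e-8 * max(1, truth.true_gca_lines.abs().max())


def test_no_dominance_means_no_sca():
    cfg = simdata.SimConfig(
        n_lines=60, n_testers=4, n_markers=300, n_qtl=40,
        dominance_ratio=0.0, residual_het_rate=0.0, missing_rate=0.0, seed=2,
    )
    g = simdata.simulate_founders(cfg)
    des = simdata.make_design(60, 4)
    _, truth = simdata.simulate_phenotypes(g, des, cfg)
    gca_var = truth.true_gca_lines.var() + truth.true_gca_testers.var()
    # purely additive trait on fully inbred parents: line x tester effects
    # are exactly additive, SCA vanishes
    assert truth.true_sca.var() < 1e-20 * gca_var + 1e-24


def test_noise_free_limit_recovers_genotypic_values():
    cfg = simdata.SimConfig(
        n_lines=30, n_testers=3, n_markers=200, n_qtl=20,
        h2_entry=1.0, gxe_ratio=0.0, seed=4,
    )
    g = simdata.simulate_founders(cfg)
    des = simdata.make_design(30, 3)
    pheno, truth = simdata.simulate_phenotypes(g, des, cfg)
    means = pheno.entry_means("trait").loc[truth.genotypic_values.index]
    centred = means - means.mean()
    gv = truth.genotypic_values - truth.genotypic_values.mean()
    np.testing.assert_allclose(centred.to_numpy(), gv.to_numpy(), atol=1e-9)


def test_sca_to_gca_ratio_matches_monte_carlo_expectation():
    """Realized SCA/GCA variance ratio over seeds agrees with a Monte-Carlo
    expectation obtained by redrawing QTL effects independently and
    decomposing the genotypic surface on the line × tester grid directly."""
    ratios = []
    for seed in range(20):
        cfg = simdata.SimConfig(
            n_lines=100, n_testers=4, n_markers=400, n_qtl=40,
            dominance_ratio=1.0, residual_het_rate=0.0, missing_rate=0.0, seed=seed,
        )
        g = simdata.simulate_founders(cfg)
        des = simdata.make_design(100, 4)
        _, truth = simdata.simulate_phenotypes(g, des, cfg)
        gca_tot = truth.true_gca_lines.var(ddof=0) + truth.true_gca_testers.var(ddof=0)
        ratios.append(truth.true_sca.var(ddof=0) / gca_tot)

    # oracle: fresh founders, fresh effect draws, direct grid decomposition
    cfg = simdata.SimConfig(
        n_lines=100, n_testers=4, n_markers=400, n_qtl=40,
        dominance_ratio=1.0, residual_het_rate=0.0, missing_rate=0.0, seed=999,
    )
    g = simdata.simulate_founders(cfg)
    des = simdata.make_design(100, 4)
    d = g.dosage.astype(float)
    li = g.sample_index(list(des.table["line"]))
    ti = g.sample_index(list(des.table["tester"]))
    pa, pb = d[li] / 2.0, d[ti] / 2.0
    x_add = pa + pb - 1.0
    x_dom = pa * (1 - pb) + pb * (1 - pa)
    rng = np.random.default_rng(12345)
    oracle = []
    for _ in range(30):
        idx = rng.choice(cfg.n_markers, cfg.n_qtl, replace=False)
        a = rng.normal(size=cfg.n_qtl)
        dd = rng.normal(size=cfg.n_qtl)
        ga = x_add[:, idx] @ a
        gd = x_dom[:, idx] @ dd
        gd = gd * np.sqrt(1.0 * np.var(ga) / np.var(gd))  # dominance_ratio = 1
        G = (ga + gd).reshape(cfg.n_lines, cfg.n_testers)
        rowm = G.mean(axis=1, keepdims=True)
        colm = G.mean(axis=0, keepdims=True)
        inter = G - rowm - colm + G.mean()
        oracle.append(np.var(inter) / (np.var(rowm) + np.var(colm)))
    mean_oracle = np.mean(oracle)
    assert abs(np.mean(ratios) - mean_oracle) < 0.5 * mean_oracle


def test_entry_heritability_realized_close_to_target():
    """Balanced ANOVA on the simulated replicates recovers the target
    entry-mean heritability within ±0.1 averaged over seeds."""
    ests = []
    for seed in range(10):
        cfg = simdata.SimConfig(
            n_lines=100, n_testers=4, n_markers=300, n_qtl=30,
            h2_entry=0.6, gxe_ratio=0.3, seed=seed,
        )
        g = simdata.simulate_founders(cfg)
        des = simdata.make_design(100, 4)
        pheno, _ = simdata.simulate_phenotypes(g, des, cfg)
        ests.append(_anova_entry_h2(pheno, "trait"))
    assert abs(np.mean(ests) - 0.6) < 0.1


def _anova_entry_h2(pheno, trait):
    """Balanced genotype × env ANOVA estimate of entry-mean heritability."""
    df = pheno.data
    e = df["env"].nunique()
    r = df["rep"].nunique()
    nh = df["hybrid"].nunique()
    cell = df.groupby(["hybrid", "env"])[trait].mean()
    gm = df.groupby("hybrid")[trait].mean()
    em = df.groupby("env")[trait].mean()
    grand = df[trait].mean()
    ms_g = r * e * ((gm - grand) ** 2).sum() / (nh - 1)
    inter = cell - gm.loc[cell.index.get_level_values(0)].to_numpy() \
        - em.loc[cell.index.get_level_values(1)].to_numpy() + grand
    ms_ge = r * (inter**2).sum() / ((nh - 1) * (e - 1))
    repm = df.groupby(["env", "rep"])[trait].mean()
    fit = cell.loc[list(zip(df["hybrid"], df["env"]))].to_numpy() \
        + repm.loc[list(zip(df["env"], df["rep"]))].to_numpy() \
        - em.loc[df["env"]].to_numpy()
    ms_err = ((df[trait].to_numpy() - fit) ** 2).sum() / (e * (r - 1) * (nh - 1))
    s2_ge = max((ms_ge - ms_err) / r, 0.0)
    s2_g = max((ms_g - ms_ge) / (r * e), 0.0)
    return s2_g / (s2_g + s2_ge / e + ms_err / (e * r))


def test_make_design_counts_and_naming():
    assert simdata.make_design(250, 4, complete=True).n_hybrids == 1000
    assert simdata.make_design(123, 8, complete=False, n_drop=60).n_hybrids == 924
    d = simdata.make_design(1, 1, complete=True)
    assert d.n_hybrids == 1
    assert d.table.iloc[0]["hybrid"] == "L001xT01"


def test_unreachable_heritability_rejected():
    cfg = simdata.SimConfig(
        n_lines=20, n_testers=2, n_markers=100, n_qtl=10,
        h2_entry=0.95, gxe_ratio=5.0, seed=0,
    )
    g = simdata.simulate_founders(cfg)
    des = simdata.make_design(20, 2)
    with pytest.raises(ValueError, match="unreachable"):
        simdata.simulate_phenotypes(g, des, cfg)


def test_write_read_round_trip(tmp_path, small_sim):
    from hybridgp import genio

    _, founders, design, pheno, truth = small_sim
    paths = simdata.write_simulation(founders, design, pheno, truth, tmp_path / "sim")
    g2 = genio.read_vcf(paths["vcf"])
    assert g2.sample_ids == founders.sample_ids
    assert np.array_equal(g2.dosage, founders.dosage)
    assert np.array_equal(g2.missing_mask, founders.missing_mask)
    truth2 = simdata.read_truth(paths["truth"])
    assert np.array_equal(truth2.qtl_indices, truth.qtl_indices)
    np.testing.assert_allclose(
        truth2.true_gca_lines.to_numpy(), truth.true_gca_lines.to_numpy()
    )
    # refuse silent overwrite
    with pytest.raises(FileExistsError):
        simdata.write_simulation(founders, design, pheno, truth, tmp_path / "sim")


def test_write_simulation_rejects_empty_design(tmp_path, small_sim):
    from hybridgp.core import MatingDesign

    _, founders, _, pheno, truth = small_sim
    empty = MatingDesign(
        table=pd.DataFrame({"line": [], "tester": [], "hybrid": []})
    )
    with pytest.raises(ValueError, match="empty"):
        simdata.write_simulation(founders, empty, pheno, truth, tmp_path / "x")
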