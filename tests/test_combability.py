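"""NC-II mixed model: REML vs ANOVA oracle, heritabilities, BLUEs, BLUPs."""

import numpy as np
import pandas as pd
import pytest

from hybridgp import combability, simdata
from hybridgp.combability import VarianceComponents
from hybridgp.core import PhenotypeTable


def small_components(**over):
    base = dict(
        sigma2_gca_l=4.0, sigma2_gca_t=1.0, sigma2_sca=2.0,
        sigma2_gca_l_x_e=0.5, sigma2_gca_t_x_e=0.5, sigma2_sca_x_e=0.5,
        sigma2_eps=6.0, t=4, r=2, e=2,
    )
    base.update(over)
    return VarianceComponents(**base)


class TestGCAHeritability:
    def test_hand_evaluated_example(self):
        vc = VarianceComponents(4, 1, 2, 0, 0, 0, 6, t=4, r=2, e=2)
        # (4+1) / (4+1 + 2/4 + 6/16) = 5 / 5.875
        assert combability.gca_heritability(vc) == pytest.approx(5 / 5.875, rel=1e-14)

    def test_noiseless_limit_is_one(self):
        vc = VarianceComponents(3, 2, 0, 0, 0, 0, 0, t=4, r=2, e=2)
        assert combability.gca_heritability(vc) == 1.0

    def test_no_gca_variance_is_zero(self):
        vc = VarianceComponents(0, 0, 2, 0, 0, 0, 6, t=4, r=2, e=2)
        assert combability.gca_heritability(vc) == 0.0

    def test_all_zero_denominator_flagged(self):
        vc = VarianceComponents(0, 0, 0, 0, 0, 0, 0, t=4, r=2, e=2)
        assert np.isnan(combability.gca_heritability(vc))

    def test_monotonicity(self):
        h = [
            combability.gca_heritability(small_components(sigma2_gca_l=v))
            for v in (1.0, 2.0, 4.0, 8.0)
        ]
        assert all(b > a for a, b in zip(h, h[1:]))
        h = [
            combability.gca_heritability(small_components(sigma2_eps=v))
            for v in (1.0, 4.0, 16.0)
        ]
        assert all(b < a for a, b in zip(h, h[1:]))

    def test_negative_component_rejected(self):
        with pytest.raises(ValueError):
            VarianceComponents(-1, 0, 0, 0, 0, 0, 0)


class TestFitNCII:
    def test_reml_matches_expected_mean_squares_oracle(self):
        ph, des = simdata.simulate_from_components(
            small_components(), n_lines=30, seed=21
        )
        vc, _ = combability.fit_ncii(ph, des, "trait")
        mom = combability.anova_mom_ncii(ph, des, "trait")
        for name in combability.TERM_NAMES:
            a, b = getattr(vc, name), getattr(mom, name)
            assert a == pytest.approx(b, rel=1e-6, abs=1e-8), name

    def test_noise_free_recovery_of_gca(self):
        cfg = simdata.SimConfig(
            n_lines=40, n_testers=4, n_markers=300, n_qtl=30,
            h2_entry=1.0, gxe_ratio=0.0, dominance_ratio=0.5, seed=8,
        )
        g = simdata.simulate_founders(cfg)
        des = simdata.make_design(40, 4)
        ph, truth = simdata.simulate_phenotypes(g, des, cfg)
        vc, tab = combability.fit_ncii(ph, des, "trait")
        est = tab.gca_lines.loc[truth.true_gca_lines.index]
        r = np.corrcoef(est, truth.true_gca_lines)[0, 1]
        assert r > 0.99

    def test_null_sca_estimated_near_zero(self):
        hits = 0
        for seed in range(20):
            ph, des = simdata.simulate_from_components(
                small_components(sigma2_sca=0.0, sigma2_sca_x_e=0.0),
                n_lines=30, seed=100 + seed,
            )
            vc, _ = combability.fit_ncii(ph, des, "trait")
            se = vc.se.get("sigma2_sca", np.nan)
            if vc.sigma2_sca <= 2 * (se if np.isfinite(se) else 0.2):
                hits += 1
        assert hits >= 18  # within 2 SE of zero in nearly all replicates

    def test_gca_blups_sum_to_zero_on_balanced_data(self):
        ph, des = simdata.simulate_from_components(small_components(), n_lines=25, seed=3)
        _, tab = combability.fit_ncii(ph, des, "trait")
        assert abs(tab.gca_lines.sum()) < 1e-8
        assert abs(tab.gca_testers.sum()) < 1e-8

    def test_single_env_drops_interactions_with_warning(self):
        ph, des = simdata.simulate_from_components(
            small_components(e=1, sigma2_gca_l_x_e=0, sigma2_gca_t_x_e=0, sigma2_sca_x_e=0),
            n_lines=20, seed=5,
        )
        with pytest.warns(UserWarning, match="single environment"):
            vc, _ = combability.fit_ncii(ph, des, "trait")
        assert vc.sigma2_gca_l_x_e == 0.0

    def test_unmatched_hybrids_rejected(self, toy_design):
        data = pd.DataFrame(
            {"hybrid": ["ghost"], "env": ["E1"], "rep": [1], "trait": [1.0]}
        )
        with pytest.raises(ValueError, match="missing from design"):
            combability.fit_ncii(PhenotypeTable(data=data), toy_design, "trait")

    def test_parameter_recovery_over_seeds(self):
        """REML recovers (4, 1, 2) GCA/SCA components within 25% relative
        error on average over seeds (reduced desk-scale layout)."""
        ests = []
        for seed in range(6):
            ph, des = simdata.simulate_from_components(
                small_components(), n_lines=60, seed=300 + seed
            )
            vc, _ = combability.fit_ncii(ph, des, "trait")
            ests.append([vc.sigma2_gca_l, vc.sigma2_gca_t, vc.sigma2_sca])
        mean_est = np.mean(ests, axis=0)
        rel_err = np.abs(mean_est - np.array([4.0, 1.0, 2.0])) / np.array([4.0, 1.0, 2.0])
        assert rel_err[0] < 0.25
        assert rel_err[2] < 0.25
        # tester GCA has only 4 levels; allow its larger sampling error
        assert rel_err[1] < 0.75


class TestEntryHeritability:
    def test_zero_noise_gives_one(self):
        ph, des = simdata.simulate_from_components(
            small_components(sigma2_gca_l_x_e=0, sigma2_gca_t_x_e=0,
                             sigma2_sca_x_e=0, sigma2_eps=0),
            n_lines=15, seed=2,
        )
        assert combability.entry_heritability(ph, "trait") == pytest.approx(1.0, abs=1e-6)

    def test_pure_noise_estimates_near_zero(self):
        rng = np.random.default_rng(0)
        ests = []
        for seed in range(5):
            ph, des = simdata.simulate_from_components(
                small_components(sigma2_gca_l=0, sigma2_gca_t=0, sigma2_sca=0,
                                 sigma2_gca_l_x_e=0, sigma2_gca_t_x_e=0,
                                 sigma2_sca_x_e=0, sigma2_eps=10.0),
                n_lines=25, seed=400 + seed,
            )
            ests.append(combability.entry_heritability(ph, "trait"))
        assert np.mean(ests) < 0.15

    def test_target_recovery(self):
        cfg = simdata.SimConfig(
            n_lines=100, n_testers=4, n_markers=300, n_qtl=30,
            h2_entry=0.7, gxe_ratio=0.2, seed=6,
        )
        g = simdata.simulate_founders(cfg)
        des = simdata.make_design(100, 4)
        ph, _ = simdata.simulate_phenotypes(g, des, cfg)
        est = combability.entry_heritability(ph, "trait")
        assert abs(est - 0.7) < 0.1

    def test_single_observation_rejected(self):
        data = pd.DataFrame(
            {"hybrid": ["h1", "h2"], "env": ["E1", "E1"], "rep": [1, 1],
             "trait": [1.0, 2.0]}
        )
        with pytest.raises(ValueError, match="replication"):
            combability.entry_heritability(PhenotypeTable(data=data), "trait")


class TestBlues:
    def test_balanced_equals_raw_means(self):
        ph, des = simdata.simulate_from_components(small_components(), n_lines=12, seed=9)
        b = combability.blues(ph, "trait")
        raw = ph.entry_means("trait")
        np.testing.assert_allclose(b.loc[raw.index], raw, atol=1e-8)

    def test_single_observation_is_itself(self):
        data = pd.DataFrame(
            {"hybrid": ["h1", "h2"], "env": ["E1", "E1"], "rep": [1, 1],
             "trait": [3.5, 4.5]}
        )
        b = combability.blues(PhenotypeTable(data=data), "trait")
        assert b["h1"] == pytest.approx(3.5)
        assert b["h2"] == pytest.approx(4.5)

    def test_unbalanced_matches_normal_equations_oracle(self):
        # three hybrids, two envs, one observation each except h3 missing E2
        data = pd.DataFrame(
            {
                "hybrid": ["h1", "h2", "h3", "h1", "h2"],
                "env": ["E1", "E1", "E1", "E2", "E2"],
                "rep": [1, 1, 1, 1, 1],
                "trait": [10.0, 12.0, 9.0, 14.0, 15.0],
            }
        )
        b = combability.blues(PhenotypeTable(data=data), "trait")
        # oracle: build the same sum-to-zero parameterization explicitly and
        # solve the normal equations directly
        X = np.array(
            [
                # h1 h2 h3 env(+1 E1 / -1 E2)
                [1, 0, 0, 1],
                [0, 1, 0, 1],
                [0, 0, 1, 1],
                [1, 0, 0, -1],
                [0, 1, 0, -1],
            ],
            dtype=float,
        )
        y = data["trait"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert b["h1"] == pytest.approx(beta[0])
        assert b["h2"] == pytest.approx(beta[1])
        assert b["h3"] == pytest.approx(beta[2])

    def test_disconnected_layout_rejected(self):
        data = pd.DataFrame(
            {
                "hybrid": ["h1", "h2"],
                "env": ["E1", "E2"],
                "rep": [1, 1],
                "trait": [1.0, 2.0],
            }
        )
        with pytest.raises(ValueError, match="disconnected"):
            combability.blues(PhenotypeTable(data=data), "trait")
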