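"""Cross-validation engine: partitions, determinism, comparisons, subsets."""

import numpy as np
import pandas as pd
import pytest

from hybridgp import evalcv
from hybridgp.evalcv import CVPlan
from hybridgp.gsmodels import ModelSpec

from conftest import make_genotypes


class TestCVPlan:
    def test_partitions_are_disjoint_and_exhaustive(self):
        plan = CVPlan(n_folds=10, n_repeats=3, seed=1)
        n = 103
        for rep in range(3):
            seen = np.zeros(n, dtype=int)
            sizes = []
            for r, fold, idx in plan.partitions(n):
                if r != rep:
                    continue
                seen[idx] += 1
                sizes.append(len(idx))
            assert (seen == 1).all()
            assert max(sizes) - min(sizes) <= 1

    def test_stratified_partitions(self):
        strata = np.repeat([0, 1], 50)
        plan = CVPlan(n_folds=5, n_repeats=1, seed=2, stratify=strata)
        for _, fold, idx in plan.partitions(100):
            # each fold receives an even share of each stratum
            assert abs((strata[idx] == 0).sum() - (strata[idx] == 1).sum()) <= 1

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            list(CVPlan(n_folds=10).partitions(15))


class TestRunCV:
    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        X = rng.choice([-1.0, 1.0], size=(60, 50))
        y = X[:, 0] + rng.normal(0, 1, 60)
        spec = ModelSpec(method="gblup", seed=5)
        plan = CVPlan(n_folds=5, n_repeats=2, seed=5)
        a = evalcv.run_cv(y, [X], spec, plan)
        b = evalcv.run_cv(y, [X], spec, plan)
        pd.testing.assert_frame_equal(a.records, b.records)
        assert a.accuracy == b.accuracy

    def test_null_response_has_near_zero_accuracy(self):
        rng = np.random.default_rng(4)
        X = rng.choice([-1.0, 1.0], size=(200, 100))
        y = rng.normal(0, 1, 200)
        run = evalcv.run_cv(
            y, [X], ModelSpec(method="gblup"), CVPlan(n_folds=10, n_repeats=3, seed=1)
        )
        assert abs(run.accuracy) < 0.1

    def test_strong_signal_recovered(self):
        rng = np.random.default_rng(5)
        X = rng.choice([-1.0, 0.0, 1.0], size=(200, 50))
        y = X[:, :5] @ np.array([2.0, -1.5, 1.0, 0.5, -2.0]) + rng.normal(0, 0.05, 200)
        run = evalcv.run_cv(
            y, [X], ModelSpec(method="gblup"), CVPlan(n_folds=10, n_repeats=1, seed=2)
        )
        assert run.accuracy >= 0.9

    def test_constant_test_fold_recorded_as_undefined(self):
        rng = np.random.default_rng(6)
        X = rng.choice([-1.0, 1.0], size=(20, 10))
        y = np.zeros(20)
        y[:2] = 1.0  # nearly constant: many folds all-zero
        run = evalcv.run_cv(
            y, [X], ModelSpec(method="gblup"), CVPlan(n_folds=5, n_repeats=1, seed=0)
        )
        assert run.n_undefined >= 1
        assert np.isfinite(run.accuracy) or run.records["r"].isna().all()


class TestCompareRuns:
    def _fake_run(self, acc, n=10):
        rec = pd.DataFrame(
            {"repeat": 0, "fold": range(n), "n_test": 5, "r": [acc] * n}
        )
        return evalcv.PredictionRun(
            spec=ModelSpec(), target="hybrid_blue", coding="A",
            records=rec, pooled_by_repeat=pd.Series({0: acc}),
        )

    def test_worked_percent_change(self):
        cmp = evalcv.compare_runs(self._fake_run(0.23), self._fake_run(0.52))
        assert cmp.percent_change == pytest.approx(126.1, abs=0.05)

    def test_identical_runs_zero(self):
        cmp = evalcv.compare_runs(self._fake_run(0.4), self._fake_run(0.4))
        assert cmp.percent_change == 0.0

    def test_halved_accuracy(self):
        cmp = evalcv.compare_runs(self._fake_run(0.6), self._fake_run(0.3))
        assert cmp.percent_change == pytest.approx(-50.0)

    def test_zero_baseline_flagged(self):
        cmp = evalcv.compare_runs(self._fake_run(0.0), self._fake_run(0.3))
        assert cmp.undefined
        assert np.isnan(cmp.percent_change)

    def test_mismatched_targets_rejected(self):
        a = self._fake_run(0.3)
        b = self._fake_run(0.4)
        b.target = "gca_line"
        with pytest.raises(ValueError, match="different targets"):
            evalcv.compare_runs(a, b)


class TestIntersectMarkers:
    def test_identical_panels_full_overlap(self):
        g = make_genotypes(np.zeros((2, 5), dtype=np.int8))
        out = evalcv.intersect_markers(g, g)
        assert len(out) == 5
        assert not out["flipped"].any()

    def test_disjoint_positions_empty(self):
        g1 = make_genotypes(np.zeros((2, 3), dtype=np.int8))
        g2 = make_genotypes(np.zeros((2, 3), dtype=np.int8))
        g2.markers["pos"] = g2.markers["pos"] + 5000
        out = evalcv.intersect_markers(g1, g2)
        assert out.empty

    def test_swapped_alleles_flagged(self):
        g1 = make_genotypes(np.zeros((2, 5), dtype=np.int8))
        g2 = make_genotypes(np.zeros((2, 5), dtype=np.int8))
        g2.markers.loc[2, ["ref", "alt"]] = ["G", "A"]  # swap one marker
        out = evalcv.intersect_markers(g1, g2)
        assert len(out) == 5
        assert out["flipped"].sum() == 1
        assert out.loc[out["flipped"], "id_1"].iloc[0] == "m3"


class TestSubsetExperiment:
    def _coded_sim(self, seed=0, n=80, m=60, n_qtl=8):
        from hybridgp.hybridcode import CodedMatrix

        rng = np.random.default_rng(seed)
        X = rng.choice([-1.0, 1.0], size=(n, m))
        qtl = list(range(n_qtl))
        y = X[:, qtl] @ rng.normal(1.0, 0.3, n_qtl) + rng.normal(0, 0.5, n)
        ids = [f"m{j}" for j in range(m)]
        cm = CodedMatrix([f"r{i}" for i in range(n)], ids, X, "parental_additive")
        return y, cm, [ids[j] for j in qtl], ids[n_qtl:]

    def test_functional_markers_beat_random(self):
        gains = []
        for seed in range(3):
            y, cm, func, pool = self._coded_sim(seed)
            exp = evalcv.subset_experiment(
                y, cm, func, pool, k=len(func),
                spec=ModelSpec(method="gblup"),
                plan=CVPlan(n_folds=5, n_repeats=1, seed=seed),
                seed=seed,
            )
            # an all-undefined random run (constant predictions) carries no
            # signal; score it as zero accuracy
            acc_r = exp.random.accuracy
            gains.append(exp.functional.accuracy - (0.0 if np.isnan(acc_r) else acc_r))
        assert np.mean(gains) > 0

    def test_k_equals_pool_uses_whole_pool(self):
        y, cm, func, pool = self._coded_sim(1)
        exp = evalcv.subset_experiment(
            y, cm, func, pool, k=len(pool),
            spec=ModelSpec(method="gblup"), plan=CVPlan(n_folds=5, n_repeats=1, seed=0),
        )
        assert sorted(exp.random_marker_ids) == sorted(pool)

    def test_seed_changes_random_subset_only(self):
        y, cm, func, pool = self._coded_sim(2)
        kw = dict(spec=ModelSpec(method="gblup"), plan=CVPlan(n_folds=5, n_repeats=1, seed=9))
        e1 = evalcv.subset_experiment(y, cm, func, pool, k=10, seed=1, **kw)
        e2 = evalcv.subset_experiment(y, cm, func, pool, k=10, seed=2, **kw)
        assert e1.random_marker_ids != e2.random_marker_ids
        pd.testing.assert_frame_equal(e1.functional.records, e2.functional.records)

    def test_overlap_rejected(self):
        y, cm, func, pool = self._coded_sim(3)
        with pytest.raises(ValueError, match="overlaps"):
            evalcv.subset_experiment(
                y, cm, func, func + pool, k=5,
                spec=ModelSpec(method="gblup"), plan=CVPlan(n_folds=5, n_repeats=1),
            )
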