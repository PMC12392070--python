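import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from decayrl.distributional import (
    CODING_CONDITIONS,
    asym_update,
    decay_value_pair,
    distribution_coding_score,
    expectile_fixed_point,
    integ_rpe,
    mean_coding_score,
    run_distributional,
    run_distributional_batch,
    segre_rpe,
)
from decayrl.tasks import make_task


class TestRPEs:
    def test_integ_uses_the_sum_only(self):
        V1 = np.array([0, 0, 0, 0, 1.5])
        V2 = np.array([0, 0, 0, 0, 0.5])
        assert integ_rpe(np.zeros(5), np.zeros(5), 5, 2.0) == 2.0
        assert integ_rpe(V1, V2, 5, 2.0) == 0.0  # sum predicts reward
        # swapping the pathways leaves the unified RPE unchanged
        assert integ_rpe(V2, V1, 4, 0.0) == integ_rpe(V1, V2, 4, 0.0)

    def test_segre_is_fully_segregated(self):
        V1 = np.full(5, 2.0)
        V2 = np.full(5, 1.5)
        for i in range(1, 6):
            R = 2.0 if i == 5 else 0.0
            assert segre_rpe(V1, V2, i, R, 1) == 0.0  # independent of V2
        assert segre_rpe(V1, V2, 5, 3.0, 2) == pytest.approx(1.5)
        assert segre_rpe(V1, V1, 3, 0.0, 1) == segre_rpe(V1, V1, 3, 0.0, 2)

    @given(h=st.lists(st.floats(-10, 10), min_size=5, max_size=5))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_integ_invariant_to_antisymmetric_shift(self, h):
        """The unified RPE depends on V1 + V2 only: adding +h to V1 and -h
        to V2 (any per-state h) leaves every delta unchanged."""
        rng = np.random.default_rng(0)
        V1 = rng.uniform(0, 3, 5)
        V2 = rng.uniform(0, 3, 5)
        h = np.array(h)
        for i in range(1, 6):
            R = 2.0 if i == 5 else 0.0
            assert integ_rpe(V1 + h, V2 - h, i, R) == pytest.approx(
                integ_rpe(V1, V2, i, R)
            )

    def test_asym_update_and_decay(self):
        V = np.zeros(5)
        assert asym_update(V, 3, 1.0, 0.15, 0.05)[2] == pytest.approx(0.15)
        assert asym_update(V, 3, -1.0, 0.15, 0.05)[2] == pytest.approx(-0.05)
        assert asym_update(V, 3, 0.0, 0.15, 0.05) == pytest.approx(V)
        V1, V2 = decay_value_pair(np.array([2.0]), np.array([1.0]), 0.01)
        assert V1[0] == pytest.approx(1.98) and V2[0] == pytest.approx(0.99)


class TestExpectileFixedPoint:
    @pytest.mark.parametrize(
        "sizes,probs,ap,am,expected",
        [
            ([1, 3], [0.5, 0.5], 0.15, 0.05, 2.5),
            ([1, 3], [0.5, 0.5], 0.05, 0.15, 1.5),
            ([0, 4], [0.5, 0.5], 0.15, 0.05, 3.0),
            ([2], [1.0], 0.15, 0.05, 2.0),
        ],
    )
    def test_against_independent_root_solver(self, sizes, probs, ap, am, expected):
        q = expectile_fixed_point(sizes, probs, ap, am)
        assert q == pytest.approx(expected, abs=1e-9)
        sizes_a = np.array(sizes, float)
        probs_a = np.array(probs, float)
        if len(sizes) > 1:
            oracle = brentq(
                lambda v: probs_a
                @ np.where(sizes_a >= v, ap * (sizes_a - v), am * (sizes_a - v)),
                min(sizes), max(sizes),
            )
            assert q == pytest.approx(oracle, abs=1e-9)

    def test_symmetric_rates_recover_the_mean(self):
        assert expectile_fixed_point([1, 3], [0.5, 0.5], 0.1, 0.1) == pytest.approx(2.0)


class TestRunners:
    def test_batch_matches_scalar_run(self, probabilistic_task):
        scalar = run_distributional("segreRPE", probabilistic_task,
                                    rng=np.random.default_rng(42))
        batch = run_distributional_batch("segreRPE", probabilistic_task, 1,
                                         rng=np.random.default_rng(42))
        assert batch["V1"][0] == pytest.approx(scalar.final_V1)
        assert batch["V2"][0] == pytest.approx(scalar.final_V2)
        last = scalar.trace[scalar.trace["trial"] == 199]
        assert batch["last_delta1"][0] == pytest.approx(last["delta1"].values)
        scalar_i = run_distributional("integRPE", probabilistic_task, kappa=0.01,
                                      rng=np.random.default_rng(7))
        batch_i = run_distributional_batch("integRPE", probabilistic_task, 1,
                                           kappa=0.01, rng=np.random.default_rng(7))
        assert batch_i["V1"][0] == pytest.approx(scalar_i.final_V1)

    def test_segre_expectile_recovery(self):
        spec = make_task(5, [(1.0, 0.5), (3.0, 0.5)], 2000)
        b = run_distributional_batch("segreRPE", spec, 50,
                                     rng=np.random.default_rng(0))
        assert b["terminal_V1"][:, 1000:].mean() == pytest.approx(2.5, abs=0.05)
        assert b["terminal_V2"][:, 1000:].mean() == pytest.approx(1.5, abs=0.05)

    def test_segre_decay_breaks_common_fixed_point(self):
        spec = make_task(5, [(2.0, 1.0)], 2000)
        no_decay = run_distributional_batch("segreRPE", spec, 10,
                                            rng=np.random.default_rng(1))
        assert no_decay["V1"].mean(axis=0) == pytest.approx(
            no_decay["V2"].mean(axis=0), abs=0.01
        )
        decay = run_distributional_batch("segreRPE", spec, 10, kappa=0.01,
                                         rng=np.random.default_rng(1))
        assert decay["V1"].mean() > decay["V2"].mean() + 0.2

    def test_integ_unbounded_growth_tamed_by_decay(self, probabilistic_task):
        spec = make_task(5, [(1.0, 0.5), (3.0, 0.5)], 2000)
        free = run_distributional_batch("integRPE", spec, 20,
                                        rng=np.random.default_rng(2),
                                        snapshot_trials=(200, 2000))
        v200 = np.abs(free["snapshots"][200][0]).max()
        v2000 = np.abs(free["snapshots"][2000][0]).max()
        assert v2000 > v200  # individual values keep drifting apart
        # ... while the sum stays anchored near the mean reward
        total = free["V1"][:, 4] + free["V2"][:, 4]
        assert np.all(np.abs(total - 2.0) < 1.0)
        tamed = run_distributional_batch("integRPE", spec, 20, kappa=0.01,
                                         rng=np.random.default_rng(2),
                                         snapshot_trials=(200, 2000))
        assert np.abs(tamed["snapshots"][2000][0]).max() < 5.0

    def test_delta_patterns_ramp_vs_abrupt(self):
        spec = make_task(5, [(1.0, 0.5), (3.0, 0.5)], 200)
        integ = run_distributional_batch("integRPE", spec, 100, kappa=0.01,
                                         rng=np.random.default_rng(3))
        mid = integ["last_delta1"][:, 1:4].mean(axis=0)
        assert np.all(mid > 0) and np.all(np.diff(mid) > 0)  # ramping RPE
        segre = run_distributional_batch("segreRPE", spec, 100,
                                         rng=np.random.default_rng(3))
        segre_mid = np.abs(segre["last_delta1"][:, 1:4].mean(axis=0))
        # abrupt (cue-locked) pattern: intermediate RPE well below the ramp
        assert segre_mid.max() < mid.min()


class TestCodingScores:
    def test_pair_count_formula(self):
        fixed = {"V1": np.tile([[1.0, 2.0]], (100, 1)),
                 "V2": np.tile([[1.0, 2.0]], (100, 1))}
        var = {"V1": np.zeros((100, 2)), "V2": np.zeros((100, 2))}
        out = distribution_coding_score(fixed, var, 0.0,
                                        np.random.default_rng(0))
        assert np.all(out["n_pairs"] == 100 * 99 // 2)

    def test_identical_difference_vectors_give_similarity_one(self):
        fixed = {"V1": np.ones((50, 3)), "V2": np.full((50, 3), 2.0)}
        var = {"V1": np.zeros((50, 3)), "V2": np.zeros((50, 3))}
        out = distribution_coding_score(fixed, var, 0.0,
                                        np.random.default_rng(0))
        assert out["cos_mean"].values == pytest.approx(np.ones(3))
        assert out["cos_sd"].values == pytest.approx(np.zeros(3), abs=1e-12)

    def test_isotropic_difference_vectors_average_to_zero(self):
        rng = np.random.default_rng(0)
        fixed = {"V1": rng.normal(size=(400, 2)), "V2": rng.normal(size=(400, 2))}
        var = {"V1": np.zeros((400, 2)), "V2": np.zeros((400, 2))}
        out = distribution_coding_score(fixed, var, 0.0,
                                        np.random.default_rng(1))
        assert np.all(np.abs(out["cos_mean"]) < 0.05)

    def test_zero_length_vectors_are_excluded_and_counted(self):
        fixed = {"V1": np.vstack([np.ones((9, 2)), np.zeros((1, 2))]),
                 "V2": np.vstack([np.ones((9, 2)), np.zeros((1, 2))])}
        var = {"V1": np.zeros((10, 2)), "V2": np.zeros((10, 2))}
        out = distribution_coding_score(fixed, var, 0.0,
                                        np.random.default_rng(0))
        assert np.all(out["n_excluded"] == 1)
        assert np.all(out["n_pairs"] == 9 * 8 // 2)

    def test_perfect_linear_coding_gives_r2_one(self):
        n = 200
        means = {"a": 0.0, "b": 2.0, "c": 2.0}
        vals = {k: {"V1": np.full((n, 3), m), "V2": np.full((n, 3), m)}
                for k, m in means.items()}
        out = mean_coding_score(vals, means, 1e-9, np.random.default_rng(0))
        assert out["r2"].values == pytest.approx(np.ones(3), abs=1e-4)

    def test_condition_independent_values_give_r2_near_zero(self):
        n = 500
        rng = np.random.default_rng(0)
        vals = {k: {"V1": rng.normal(size=(n, 2)), "V2": rng.normal(size=(n, 2))}
                for k in ("a", "b", "c")}
        out = mean_coding_score(vals, {"a": 0.0, "b": 2.0, "c": 2.0}, 0.05,
                                np.random.default_rng(1))
        assert np.all(out["r2"] < 0.01)

    def test_estimators_agree_when_patterns_align(self):
        n = 300
        means = {"a": 0.0, "b": 2.0, "c": 2.0}
        vals = {k: {"V1": np.full((n, 2), m), "V2": np.full((n, 2), m)}
                for k, m in means.items()}
        uni = mean_coding_score(vals, means, 0.05, np.random.default_rng(2),
                                estimator="univariate")
        multi = mean_coding_score(vals, means, 0.05, np.random.default_rng(2),
                                  estimator="multiple")
        assert uni["r2"].values == pytest.approx(multi["r2"].values, abs=0.02)
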