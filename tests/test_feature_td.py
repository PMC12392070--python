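import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from decayrl.feature_td import (
    decay_weights,
    make_features,
    run_feature_td,
    run_navigation,
    sr_feature_td_error,
    state_value,
    update_weights,
)
from decayrl.tasks import make_task


class TestMakeFeatures:
    def test_sr_rows_at_gamma_one(self):
        X = make_features("SR", 5, gamma=1.0).X
        assert X[0].tolist() == [1, 1, 1, 1, 1]
        assert X[4].tolist() == [0, 0, 0, 0, 1]
        assert np.allclose(X, np.triu(np.ones((5, 5))))

    def test_pr_rows_at_gamma_one(self):
        X = make_features("PR", 5, gamma=1.0).X
        assert X[0].tolist() == [1, 0, 0, 0, 0]
        assert X[4].tolist() == [1, 1, 1, 1, 1]

    def test_sr_discounted_entries(self):
        X = make_features("SR", 4, gamma=0.5).X
        assert X[0].tolist() == [1, 0.5, 0.25, 0.125]

    @pytest.mark.parametrize("kind", ["sparse", "dense"])
    def test_random_features_unit_norm(self, kind, rng):
        fs = make_features(kind, 5, 100, 10, rng=rng)
        norms = np.linalg.norm(fs.X, axis=1)
        assert norms == pytest.approx(np.ones(5))
        nnz = (fs.X != 0).sum(axis=1)
        if kind == "sparse":
            assert np.all(nnz == 10)
        else:
            assert np.all(nnz == 100)


class TestValueAndWeightOps:
    def test_initial_weights_give_zero_value(self, rng):
        x = rng.uniform(0, 1, 10)
        w = np.full(10, 0.5)
        assert state_value(w, 0.5, x) == pytest.approx(0.0)

    def test_direct_formula_and_linearity(self):
        assert state_value(np.array([1.0, 0.5]), 0.5, np.array([1.0, 0.0])) == 0.5
        w = np.array([0.9, 0.1, 0.4])
        x = np.array([0.2, 0.0, 1.3])
        assert state_value(w, 0.5, 3.0 * x) == pytest.approx(
            3.0 * state_value(w, 0.5, x)
        )

    def test_update_formula_and_clamp(self):
        w = np.array([0.5, 0.5])
        out = update_weights(w, 0.2, np.array([1.0, 0.0]), 0.15, 0.075)
        assert out == pytest.approx([0.53, 0.5])
        assert update_weights(w, 0.0, np.ones(2), 0.15, 0.075) == pytest.approx(w)
        clamped = update_weights(np.zeros(2), -1.0, np.ones(2), 0.15, 0.075)
        assert np.all(clamped == 0.0)

    def test_update_norm_scaling_matters_for_sr(self):
        # SR feature rows are not unit norm, so the ||x||^2 division matters
        x = np.ones(4)  # squared norm 4
        out = update_weights(np.zeros(4), 1.0, x, 0.15, 0.075)
        assert out == pytest.approx(np.full(4, 0.15 / 4))

    def test_decay_is_toward_baseline_from_both_sides(self):
        assert decay_weights(np.array([0.5]), 0.5, 0.01) == pytest.approx([0.5])
        assert decay_weights(np.array([0.7]), 0.5, 0.01) == pytest.approx([0.698])
        assert decay_weights(np.array([0.3]), 0.5, 0.01) == pytest.approx([0.302])

    @given(
        seed=st.integers(0, 10_000),
        deltas=st.lists(st.floats(-5, 5), min_size=1, max_size=30),
    )
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_weights_stay_nonnegative_under_any_sequence(self, seed, deltas):
        r = np.random.default_rng(seed)
        x = r.uniform(0, 1, 8)
        x /= np.linalg.norm(x)
        w = np.full(8, 0.5)
        for d in deltas:
            w = update_weights(w, d, x, 0.15, 0.075)
            w = decay_weights(w, 0.5, 0.01)
            assert np.all(w >= 0)


class TestRunFeatureTD:
    def test_no_decay_recovers_tabular_values(self, rng):
        """With linearly independent features and kappa = 0 the feature-TD
        steady state reproduces the tabular geometric value profile."""
        spec = make_task(5, [(1.0, 1.0)], 2000, 0.9)
        feats = make_features("sparse", 5, 100, 10, rng=rng)
        tr = run_feature_td(spec, feats, 0.15, 0.075, kappa=0.0, rng=rng)
        last = tr[(tr["trial"] == 1999) & (tr["step"] > 0)]
        expected = 0.9 ** (5 - np.arange(1, 6))
        assert last["value"].values == pytest.approx(expected, abs=1e-2)

    def test_sr_flat_intermediate_but_sustained_reward(self, fig1_task):
        feats = make_features("SR", 5, gamma=1.0)
        tr = run_feature_td(fig1_task, feats, 0.15, 0.075, kappa=0.01)
        last = tr[tr["trial"] == 199].set_index("step")["delta"]
        assert np.all(np.abs(last.loc[2:4]) < 0.01)  # no ramp
        assert last.loc[5] > 0.05  # sustained reward response

    def test_pr_ramps_down(self, fig1_task):
        feats = make_features("PR", 5, gamma=1.0)
        tr = run_feature_td(fig1_task, feats, 0.15, 0.075, kappa=0.01)
        last = tr[tr["trial"] == 199].set_index("step")["delta"]
        mid = last.loc[2:4].values
        assert np.all(np.diff(mid) < 0)  # decreasing over intermediate states

    def test_dense_slow_learning_responds_to_cue_and_reward(self):
        """With a small symmetric learning rate, learning of the {0.5, 1.5}
        probabilistic reward is still incomplete after 100 trials: the final
        trial shows a positive response at cue and at reward for both
        realized reward sizes."""
        import pandas as pd

        spec = make_task(5, [(0.5, 0.5), (1.5, 0.5)], 100, 1.0)
        rows = []
        for s in range(30):
            r = np.random.default_rng(300 + s)
            feats = make_features("dense", 5, 100, rng=r)
            tr = run_feature_td(spec, feats, a_plus=0.005, a_minus=0.005,
                                kappa=0.0, rng=r)
            rows.append(tr[tr["trial"] == 99])
        last = pd.concat(rows)
        by = last.groupby(["reward", "step"])["delta"].mean()
        for reward in (0.5, 1.5):
            assert by.loc[(reward, 0)] > 0.05  # cue response
            assert by.loc[(reward, 5)] > 0.05  # reward response


class TestSRFeatureError:
    def test_punctate_initial_error(self):
        X = np.eye(5)
        err = sr_feature_td_error(X, 1, 1.0)
        assert err.tolist() == [0, 1, 0, 0, 0]

    def test_terminal_error_is_zero(self):
        X = np.eye(5)
        assert np.all(sr_feature_td_error(X, 5, 1.0) == 0)

    def test_exact_sr_is_fixed_point(self):
        X = make_features("SR", 5, gamma=1.0).X
        for i in range(1, 6):
            assert sr_feature_td_error(X, i, 1.0) == pytest.approx(np.zeros(5))


class TestNavigation:
    def test_ramp_fades_and_features_approach_sr(self, rng):
        nav = run_navigation(rng=rng)
        sm = nav.session_mean_delta()
        amp = sm.mean(axis=1).values  # mean intermediate-state RPE per session
        assert np.all(np.diff(amp) < 0)  # monotone fading across 9 sessions
        sr = make_features("SR", 5, gamma=1.0).X
        dists = [np.linalg.norm(X - sr) for X in nav.session_features]
        assert np.all(np.diff(dists) < 0)

    def test_first_trial_ramp_is_reward_proximal(self, rng):
        nav = run_navigation(rng=rng)
        t0 = nav.trace[(nav.trace["trial"] == 0) & (nav.trace["step"] > 0)]
        d = t0.set_index("step")["delta"]
        assert d.loc[5] == pytest.approx(1.0)  # unpredicted reward
        assert np.all(np.abs(d.loc[1:4]) < 1e-9)  # nothing earlier yet
        later = nav.trace[nav.trace["trial"].between(1, 8)]
        mid = later[later["state"].isin([2, 3, 4])]["delta"].mean()
        assert mid > 0  # ramp spreads backwards over the next trials

    def test_frozen_features_keep_ramp(self, rng):
        nav = run_navigation(a_sr=0.0, rng=rng)
        sm = nav.session_mean_delta()
        # without SR learning the ramp persists at full amplitude
        assert sm.iloc[-1].mean() > 0.9 * sm.iloc[1].mean()
        assert np.allclose(nav.final_features, np.eye(5))

    def test_orderings_agree_at_small_learning_rates(self, rng):
        a = run_navigation(order="features_first", rng=np.random.default_rng(3))
        b = run_navigation(order="value_first", rng=np.random.default_rng(3))
        pa = a.session_mean_delta().values
        pb = b.session_mean_delta().values
        assert np.max(np.abs(pa - pb)) < 1e-3
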