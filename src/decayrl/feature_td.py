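"""Linear-function-approximation TD with non-negative weights and weight decay.

States are represented by feature vectors ``x_i`` and the state value is a
weighted sum of features with subtraction of a constant vector:

    V(S_i) = w . x_i - w0 * sum_j x_{i,j}

``w`` is initialised to the all-``w0`` vector (so initial values are zero) and
is constrained non-negative; the constant subtraction lets effective weights
go negative, which biologically would be carried by striatal inhibitory
interneurons.  Updates use asymmetric learning rates for positive vs negative
TD-RPE (D1-receptor-like plasticity), normalised by the squared feature norm:

    w <- max(0, w + a_f * delta * x_i / ||x_i||^2),   a_f = a+ if delta >= 0 else a-

and weight decay pulls every weight back toward its initial value:

    w_j <- w0 + (1 - kappa)(w_j - w0)

Representations
---------------
sparse   100-dim, 10 pseudorandomly chosen positive entries, unit norm
dense    100-dim, all entries positive pseudorandom, unit norm
SR       n-dim successor representation, x_{i,j} = gamma^(j-i) for j >= i
PR       n-dim predecessor representation, x_{i,j} = gamma^(i-j) for j <= i
learned  starts punctate (identity) and is shaped toward the SR online by TD
         learning of the features themselves (the navigation simulation)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tasks import TaskSpec, sample_reward

__all__ = [
    "FeatureSet",
    "make_features",
    "state_value",
    "update_weights",
    "decay_weights",
    "run_feature_td",
    "sr_feature_td_error",
    "run_navigation",
    "NavigationResult",
]

FEATURE_KINDS = ("sparse", "dense", "SR", "PR")


@dataclass(frozen=True)
class FeatureSet:
    """Per-state feature vectors, one row of ``X`` per within-trial state."""

    kind: str
    X: np.ndarray  # (n_states, m)

    @property
    def n_states(self) -> int:
        return self.X.shape[0]

    @property
    def dim(self) -> int:
        return self.X.shape[1]


def make_features(
    kind: str,
    n_states: int,
    dim: int = 100,
    n_active: int = 10,
    gamma: float = 1.0,
    rng: np.random.Generator | None = None,
) -> FeatureSet:
    """Build the feature matrix for one of the fixed representations.

    ``gamma`` here is the occupancy discount used to construct the SR/PR
    matrices (set to 1 in the reference protocols) and is independent of the
    value-learning discount factor.
    """
    if kind in ("sparse", "dense"):
        if rng is None:
            raise ValueError(f"{kind} features require an rng")
        X = np.zeros((n_states, dim))
        for i in range(n_states):
            if kind == "sparse":
                if n_active > dim:
                    raise ValueError("n_active must not exceed dim")
                support = rng.choice(dim, size=n_active, replace=False)
                X[i, support] = rng.uniform(0.0, 1.0, size=n_active)
            else:
                X[i] = rng.uniform(0.0, 1.0, size=dim)
            X[i] /= np.linalg.norm(X[i])
        return FeatureSet(kind, X)
    if kind in ("SR", "PR"):
        j = np.arange(n_states)
        diff = j[None, :] - j[:, None]  # j - i
        if kind == "SR":
            X = np.where(diff >= 0, float(gamma) ** np.maximum(diff, 0), 0.0)
        else:
            X = np.where(diff <= 0, float(gamma) ** np.maximum(-diff, 0), 0.0)
        return FeatureSet(kind, X)
    raise ValueError(f"unknown feature kind: {kind!r}")


def state_value(w: np.ndarray, w0: float, x: np.ndarray) -> float:
    """Value of a state: ``w . x - w0 * sum(x)``."""
    w = np.asarray(w, dtype=float)
    x = np.asarray(x, dtype=float)
    if w.shape != x.shape:
        raise ValueError("weight/feature dimension mismatch")
    return float(w @ x - w0 * x.sum())


def update_weights(
    w: np.ndarray,
    delta: float,
    x: np.ndarray,
    a_plus: float,
    a_minus: float,
) -> np.ndarray:
    """Norm-normalised asymmetric TD update with a non-negativity clamp."""
    sq = float(np.asarray(x, dtype=float) @ np.asarray(x, dtype=float))
    if sq == 0.0:
        raise ValueError("zero feature vector")
    a_f = a_plus if delta >= 0 else a_minus
    return np.maximum(0.0, np.asarray(w, dtype=float) + a_f * delta * np.asarray(x) / sq)


def decay_weights(w: np.ndarray, w0: float, kappa: float) -> np.ndarray:
    """Two-sided decay of each weight toward the baseline ``w0``."""
    if not 0.0 <= kappa < 1.0:
        raise ValueError("kappa must lie in [0, 1)")
    w = np.asarray(w, dtype=float)
    return w0 + (1.0 - kappa) * (w - w0)


def run_feature_td(
    spec: TaskSpec,
    features: FeatureSet,
    a_plus: float = 0.15,
    a_minus: float = 0.075,
    kappa: float = 0.0,
    w0: float = 0.5,
    rng: np.random.Generator | None = None,
    cue_response: str = "discounted",
) -> pd.DataFrame:
    """Trial loop for a fixed feature representation.

    Same structure as the punctate runner: per trial, step 0 records the cue
    response ``gamma * V(S_1)`` from the pre-trial weights; then for
    i = 1..n the pre-update TD-RPE is recorded, the weights are updated and
    then decayed toward baseline.  Returns the long-format trace
    ``(trial, step, state, reward, delta, value)``.
    """
    if features.n_states != spec.n_states:
        raise ValueError("feature set does not match task n_states")
    if rng is None:
        rng = np.random.default_rng(0)
    n = spec.n_states
    gamma = spec.gamma
    X = features.X
    w = np.full(features.dim, w0)
    col_sums = X.sum(axis=1)

    def values() -> np.ndarray:
        return X @ w - w0 * col_sums

    records = np.empty((spec.n_trials * (n + 1), 6))
    row = 0
    for trial in range(spec.n_trials):
        r = sample_reward(spec, rng)
        V = values()
        cue = (gamma if cue_response == "discounted" else 1.0) * V[0]
        records[row] = (trial, 0, 0, r, cue, 0.0)
        row += 1
        for i in range(1, n + 1):
            R_i = r if i == n else 0.0
            V = values()
            if i == n:
                d = R_i - V[i - 1]
            else:
                d = R_i + gamma * V[i] - V[i - 1]
            records[row] = (trial, i, i, r, d, V[i - 1])
            row += 1
            w = update_weights(w, d, X[i - 1], a_plus, a_minus)
            w = decay_weights(w, w0, kappa)

    df = pd.DataFrame(
        records, columns=["trial", "step", "state", "reward", "delta", "value"]
    )
    df[["trial", "step", "state"]] = df[["trial", "step", "state"]].astype(int)
    return df


def sr_feature_td_error(X: np.ndarray, i: int, gamma: float = 1.0) -> np.ndarray:
    """TD error vector of SR features at 1-based state ``i``.

    ``delta_SR_i = I_i + gamma * x_{i+1} - x_i`` with the successor term
    dropped at the terminal state.  Because the terminal row is initialised
    to the indicator ``I_n``, the terminal error is identically zero and the
    terminal row never changes.
    """
    n = X.shape[0]
    if not 1 <= i <= n:
        raise IndexError(f"state index {i} out of range 1..{n}")
    I_i = np.zeros(n)
    I_i[i - 1] = 1.0
    if i == n:
        return I_i - X[i - 1]
    return I_i + gamma * X[i] - X[i - 1]


@dataclass
class NavigationResult:
    """Output of the reward-navigation simulation with online SR learning."""

    trace: pd.DataFrame  # long-format (trial, step, state, reward, delta, value)
    session_features: np.ndarray  # (n_sessions, n, n) feature matrix at session ends
    final_features: np.ndarray  # (n, n)
    session_len: int

    def session_mean_delta(self, states=(2, 3, 4)) -> pd.DataFrame:
        """Session-averaged delta at the given states (post-start .. pre-goal)."""
        df = self.trace[self.trace["state"].isin(states)].copy()
        df["session"] = df["trial"] // self.session_len
        return (
            df.groupby(["session", "state"])["delta"].mean().unstack("state")
        )


def run_navigation(
    reward_size: float = 1.0,
    n_trials: int = 360,
    session_len: int = 40,
    a_plus: float = 0.15,
    a_minus: float = 0.075,
    kappa: float = 0.01,
    a_sr: float = 0.001,
    w0: float = 0.5,
    gamma: float = 1.0,
    n_states: int = 5,
    order: str = "features_first",
    rng: np.random.Generator | None = None,
) -> NavigationResult:
    """Linear-track reward navigation with SR features learned online.

    The representation starts punctate (identity matrix) and each visited
    state's feature row is nudged toward the successor representation by the
    feature TD error (learning rate ``a_sr``), while value weights learn and
    decay exactly as in :func:`run_feature_td`.  With the default ordering
    the feature update precedes the value computation within a time-step;
    ``order="value_first"`` swaps them (the two interleavings are not
    distinguishable at these learning rates but both are available).
    """
    if order not in ("features_first", "value_first"):
        raise ValueError("order must be 'features_first' or 'value_first'")
    if rng is None:
        rng = np.random.default_rng(0)
    n = n_states
    X = np.eye(n)
    w = np.full(n, w0)

    n_sessions = n_trials // session_len
    session_features = np.empty((n_sessions, n, n))
    records = np.empty((n_trials * (n + 1), 6))
    row = 0
    for trial in range(n_trials):
        r = reward_size
        V = X @ w - w0 * X.sum(axis=1)
        records[row] = (trial, 0, 0, r, gamma * V[0], 0.0)
        row += 1
        for i in range(1, n + 1):
            R_i = r if i == n else 0.0
            if order == "features_first":
                X[i - 1] += a_sr * sr_feature_td_error(X, i, gamma)
            V = X @ w - w0 * X.sum(axis=1)
            if i == n:
                d = R_i - V[i - 1]
            else:
                d = R_i + gamma * V[i] - V[i - 1]
            records[row] = (trial, i, i, r, d, V[i - 1])
            row += 1
            w = update_weights(w, d, X[i - 1], a_plus, a_minus)
            w = decay_weights(w, w0, kappa)
            if order == "value_first":
                X[i - 1] += a_sr * sr_feature_td_error(X, i, gamma)
        if (trial + 1) % session_len == 0:
            session_features[(trial + 1) // session_len - 1] = X

    trace = pd.DataFrame(
        records, columns=["trial", "step", "state", "reward", "delta", "value"]
    )
    trace[["trial", "step", "state"]] = trace[["trial", "step", "state"]].astype(int)
    return NavigationResult(
        trace=trace,
        session_features=session_features,
        final_features=X,
        session_len=session_len,
    )
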