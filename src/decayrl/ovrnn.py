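"""Online value-RNN (oVRNN) with random feedback and biological constraints.

A 40-unit sigmoidal RNN (association cortex) receives five binary observation
units (cue units 1-4 and a reward unit) and feeds a value readout
``v(t) = w . x(t)`` (striatum).  Both the readout weights and the recurrent /
feedforward weights are trained online by the same scalar TD-RPE

    delta(t) = r(t) + gamma * v(t+1) - v(t)

(dopamine broadcast).  The readout update is Hebbian with a non-negativity
clamp, followed by an optional per-step decay of the value weights toward
zero (``dr``).  The recurrent/feedforward update replaces backprop's
symmetric feedback with fixed random feedback gains ``c_i`` in [0, 1] and the
sigmoid derivative ``x(1-x)`` with a monotonic-plus-saturation factor
(``x(1-x)`` below 0.5 activity, the constant 0.25 above — continuous at 0.5).

Learning is continuous across trials including inter-trial intervals, so the
value-weight decay also applies during ITI steps.  The heavy per-step loop is
compiled with numba; :func:`rnn_step` and the other small operations are the
plain-NumPy reference path, and the two are held equal by a test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap

from .tasks import CUE_DURATION, ObservationStream, make_observation_stream

__all__ = [
    "RNNState",
    "rnn_step",
    "readout_value",
    "ovrnn_td_rpe",
    "update_value_weights",
    "decay_value_weights",
    "update_rnn_weights",
    "run_ovrnn",
    "OVRNNResult",
    "init_rnn_state",
    "has_cue_peak",
]

N_UNITS = 40
N_OBS = 5


@dataclass
class RNNState:
    """Weights and activity of the online value-RNN."""

    A: np.ndarray  # (40, 40) recurrent weights
    B: np.ndarray  # (40, 5) feedforward weights
    w: np.ndarray  # (40,) non-negative value weights
    c: np.ndarray  # (40,) fixed random feedback gains in [0, 1]
    x: np.ndarray  # (40,) unit activities in (0, 1)
    gamma: float = 0.8
    a_rnn: float = 0.1
    a_value: float = 0.03
    dr: float = 0.0


def init_rnn_state(rng: np.random.Generator, dr: float = 0.0) -> RNNState:
    """Standard initialisation: A, B standard normal; x, c uniform [0,1]; w = 0."""
    return RNNState(
        A=rng.standard_normal((N_UNITS, N_UNITS)),
        B=rng.standard_normal((N_UNITS, N_OBS)),
        w=np.zeros(N_UNITS),
        c=rng.uniform(0.0, 1.0, N_UNITS),
        x=rng.uniform(0.0, 1.0, N_UNITS),
        dr=dr,
    )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def rnn_step(state: RNNState, o: np.ndarray) -> np.ndarray:
    """Next activity vector ``x(t+1) = f(A x(t) + B o(t))`` (does not mutate state)."""
    o = np.asarray(o, dtype=float)
    if o.shape != (state.B.shape[1],):
        raise ValueError("observation vector has wrong dimension")
    return _sigmoid(state.A @ state.x + state.B @ o)


def readout_value(w: np.ndarray, x: np.ndarray) -> float:
    """Striatal value readout ``v = w . x``."""
    return float(np.asarray(w) @ np.asarray(x))


def ovrnn_td_rpe(r: float, v_t: float, v_t1: float, gamma: float = 0.8) -> float:
    """One-step TD-RPE ``delta(t) = r(t) + gamma v(t+1) - v(t)``."""
    return float(r + gamma * v_t1 - v_t)


def update_value_weights(
    w: np.ndarray, delta: float, x: np.ndarray, a_value: float = 0.03
) -> np.ndarray:
    """Clamped Hebbian readout update ``w_j <- max(0, w_j + a_value delta x_j)``."""
    return np.maximum(0.0, np.asarray(w, dtype=float) + a_value * delta * np.asarray(x))


def decay_value_weights(w: np.ndarray, dr: float) -> np.ndarray:
    """Per-step value-weight decay toward zero."""
    return np.asarray(w, dtype=float) * (1.0 - dr)


def _plasticity_factor(x_now: np.ndarray) -> np.ndarray:
    """Monotonic + saturation replacement of the sigmoid derivative."""
    return np.where(x_now <= 0.5, x_now * (1.0 - x_now), 0.25)


def update_rnn_weights(
    A: np.ndarray,
    B: np.ndarray,
    delta: float,
    x_prev: np.ndarray,
    o_prev: np.ndarray,
    x_now: np.ndarray,
    c: np.ndarray,
    a_rnn: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Random-feedback update of the recurrent and feedforward weights.

    The postsynaptic factor at unit i is ``x_i(t)(1 - x_i(t))`` while
    ``x_i(t) <= 0.5`` and the saturated constant 0.25 above; the presynaptic
    factors are the previous-step activities/observations; ``c_i`` is the
    fixed random feedback gain replacing backprop's symmetric feedback.
    """
    g = a_rnn * delta * _plasticity_factor(np.asarray(x_now)) * np.asarray(c)
    return (
        np.asarray(A, dtype=float) + np.outer(g, x_prev),
        np.asarray(B, dtype=float) + np.outer(g, o_prev),
    )


@njit(cache=True)
def _simulate_stream(
    o, r, A, B, w, c, x, gamma, a_value, a_rnn, dr
):  # pragma: no cover - compiled
    T = o.shape[0]
    n = A.shape[0]
    delta = np.zeros(T)
    v_trace = np.zeros(T)
    x_prev = x.copy()
    o_prev = np.zeros(o.shape[1])
    for t in range(T - 1):
        # step RNN: x_next = f(A x + B o(t))
        z = A @ x + B @ o[t]
        x_next = 1.0 / (1.0 + np.exp(-z))
        v_t = w @ x
        v_t1 = w @ x_next
        d = r[t] + gamma * v_t1 - v_t
        delta[t] = d
        v_trace[t] = v_t
        # value-weight update with x(t), then decay
        for j in range(n):
            wj = w[j] + a_value * d * x[j]
            if wj < 0.0:
                wj = 0.0
            w[j] = wj * (1.0 - dr)
        # recurrent/feedforward update with (t-1, t) activities
        if t > 0:
            for i in range(n):
                xi = x[i]
                fac = xi * (1.0 - xi) if xi <= 0.5 else 0.25
                g = a_rnn * d * fac * c[i]
                if g != 0.0:
                    for j in range(n):
                        A[i, j] += g * x_prev[j]
                    for k in range(o.shape[1]):
                        B[i, k] += g * o_prev[k]
        x_prev = x
        o_prev = o[t]
        x = x_next
    v_trace[T - 1] = w @ x
    return delta, v_trace


def _simulate_stream_py(o, r, A, B, w, c, x, gamma, a_value, a_rnn, dr):
    """Pure-NumPy reference simulation built from the unit operations."""
    T = o.shape[0]
    state = RNNState(A=A, B=B, w=w, c=c, x=x, gamma=gamma,
                     a_rnn=a_rnn, a_value=a_value, dr=dr)
    delta = np.zeros(T)
    v_trace = np.zeros(T)
    x_prev = state.x.copy()
    o_prev = np.zeros(o.shape[1])
    for t in range(T - 1):
        x_next = rnn_step(state, o[t])
        v_t = readout_value(state.w, state.x)
        v_t1 = readout_value(state.w, x_next)
        d = ovrnn_td_rpe(r[t], v_t, v_t1, gamma)
        delta[t] = d
        v_trace[t] = v_t
        state.w = decay_value_weights(
            update_value_weights(state.w, d, state.x, a_value), dr
        )
        if t > 0:
            state.A, state.B = update_rnn_weights(
                state.A, state.B, d, x_prev, o_prev, state.x, state.c, a_rnn
            )
        x_prev = state.x
        o_prev = o[t]
        state.x = x_next
    v_trace[T - 1] = readout_value(state.w, state.x)
    return delta, v_trace


@dataclass
class OVRNNResult:
    """Trial-aligned traces from one oVRNN simulation."""

    stream: ObservationStream = field(repr=False)
    delta: np.ndarray = field(repr=False)  # (T,) per-step TD-RPE
    value: np.ndarray = field(repr=False)  # (T,) per-step value v(t)
    final_state: RNNState | None = None

    def trial_aligned(self, last_k: int = 100) -> pd.DataFrame:
        """Per-trial delta and value at the 5 trial steps (4 cue + reward).

        Step 0 is the first cue step, step 4 the reward step.  Only the last
        ``last_k`` complete trials are returned (the trained regime).
        """
        s = self.stream
        first = max(0, s.n_trials - last_k)
        rows = []
        for trial in range(first, s.n_trials):
            t0 = s.cue_onsets[trial]
            for k in range(CUE_DURATION + 1):
                rows.append((trial, k, self.delta[t0 + k], self.value[t0 + k]))
        return pd.DataFrame(rows, columns=["trial", "step", "delta", "value"])

    def mean_profile(self, last_k: int = 100) -> pd.DataFrame:
        """Mean delta/value per trial step over the last ``last_k`` trials."""
        return self.trial_aligned(last_k).groupby("step")[["delta", "value"]].mean()


def has_cue_peak(profile: np.ndarray, include_reward: bool = False) -> bool:
    """Whether the trial-aligned TD-RPE profile peaks at the cue step.

    ``profile`` is the per-step mean delta (step 0 = cue onset, last step =
    reward).  By default the comparison spans cue through the pre-reward
    step: with value-weight decay the reward step carries a sustained
    positive response in every condition, and the cue-peak-versus-ramping
    contrast concerns the shape of the profile leading up to reward.
    """
    profile = np.asarray(profile, dtype=float)
    span = profile if include_reward else profile[:-1]
    return int(np.argmax(span)) == 0


def run_ovrnn(
    cue_type: str,
    iti_kind: str,
    dr: float = 0.0,
    n_trials: int = 1000,
    rng: np.random.Generator | None = None,
    gamma: float = 0.8,
    a_rnn: float = 0.1,
    a_value: float = 0.03,
    use_numba: bool = True,
    keep_state: bool = False,
) -> OVRNNResult:
    """Train an oVRNN on a continuous cue-reward stream and return its traces.

    ``dr`` is the per-step value-weight decay (0 or 0.001 in the reference
    conditions).  All randomness (initial weights/activities, feedback gains
    and ITI draws) flows through ``rng``.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    stream = make_observation_stream(cue_type, iti_kind, n_trials, rng)
    state = init_rnn_state(rng, dr=dr)
    sim = _simulate_stream if (use_numba and _HAVE_NUMBA) else _simulate_stream_py
    delta, value = sim(
        stream.o,
        stream.rewards.astype(float),
        state.A,
        state.B,
        state.w,
        state.c,
        state.x.copy(),
        gamma,
        a_value,
        a_rnn,
        dr,
    )
    return OVRNNResult(
        stream=stream,
        delta=delta,
        value=value,
        final_state=state if keep_state else None,
    )
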