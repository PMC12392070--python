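"""Tabular TD(0) learning with multiplicative value decay.

Each within-trial timing is its own (punctate) state.  At every time-step the
agent computes the TD reward-prediction error

    delta_i = R_i + gamma * V(S_{i+1}) - V(S_i)        (gamma term dropped at i = n)

updates the visited state's value by ``a * delta_i``, and then *all* state
values decay multiplicatively, ``V <- (1 - kappa) V``.  Decay models gradual
loss of dopamine-dependent plasticity and is applied only during task trials.

Reported cue response
---------------------
After learning, the printed delta formula yields no transient at the cue
state itself (its value is fully predicted by... nothing before it), yet a
phasic dopamine-like cue response is a robust experimental feature.  We model
an implicit pre-cue state whose value is permanently zero and never updated,
so the cue response is ``gamma * V(S_1)`` evaluated at trial start.  It is
recorded as step 0 of each trial (``state`` 0) in the returned trace.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .tasks import TaskSpec, sample_reward

__all__ = [
    "ValueState",
    "td_rpe",
    "update_value",
    "decay_values",
    "run_punctate",
    "punctate_fixed_point",
]


@dataclass(frozen=True)
class ValueState:
    """Tabular state values with learning and decay rates."""

    V: np.ndarray
    a: float = 0.15
    kappa: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "V", np.asarray(self.V, dtype=float))
        if self.a <= 0:
            raise ValueError("learning rate a must be positive")
        if not 0.0 <= self.kappa < 1.0:
            raise ValueError("kappa must lie in [0, 1)")


def td_rpe(V: np.ndarray, i: int, R_i: float, gamma: float) -> float:
    """TD-RPE at 1-based state index ``i``; the successor term is dropped at i = n."""
    n = len(V)
    if not 1 <= i <= n:
        raise IndexError(f"state index {i} out of range 1..{n}")
    if i == n:
        return float(R_i - V[i - 1])
    return float(R_i + gamma * V[i] - V[i - 1])


def update_value(V: np.ndarray, i: int, delta: float, a: float) -> np.ndarray:
    """Return a copy of ``V`` with entry ``i`` (1-based) moved by ``a * delta``."""
    out = np.array(V, dtype=float)
    out[i - 1] += a * delta
    return out


def decay_values(V: np.ndarray, kappa: float) -> np.ndarray:
    """Multiplicative decay of every state value: ``V <- (1 - kappa) V``."""
    if not 0.0 <= kappa < 1.0:
        raise ValueError("kappa must lie in [0, 1)")
    return np.asarray(V, dtype=float) * (1.0 - kappa)


def run_punctate(
    spec: TaskSpec,
    a: float = 0.15,
    kappa: float = 0.0,
    rng: np.random.Generator | None = None,
    cue_response: str = "discounted",
) -> pd.DataFrame:
    """Simulate punctate-representation TD learning over ``spec.n_trials`` trials.

    Within each trial, for i = 1..n: record the pre-update TD-RPE, update
    ``V(S_i)``, then decay all values once.  The trial's cue response
    (``gamma * V(S_1)``, or raw ``V(S_1)`` with ``cue_response="raw"``) is
    recorded before the first within-trial step as step 0.

    Returns a long-format trace with columns
    ``(trial, step, state, reward, delta, value)`` where ``delta`` at step 0
    holds the cue response and ``value`` holds the pre-update value of the
    visited state.
    """
    if cue_response not in ("discounted", "raw"):
        raise ValueError("cue_response must be 'discounted' or 'raw'")
    if rng is None:
        rng = np.random.default_rng(0)
    n = spec.n_states
    gamma = spec.gamma
    V = np.zeros(n)

    records = np.empty((spec.n_trials * (n + 1), 6))
    row = 0
    for trial in range(spec.n_trials):
        r = sample_reward(spec, rng)
        cue = (gamma if cue_response == "discounted" else 1.0) * V[0]
        records[row] = (trial, 0, 0, r, cue, 0.0)
        row += 1
        for i in range(1, n + 1):
            R_i = r if i == n else 0.0
            d = td_rpe(V, i, R_i, gamma)
            records[row] = (trial, i, i, r, d, V[i - 1])
            row += 1
            V[i - 1] += a * d
            V *= 1.0 - kappa

    df = pd.DataFrame(
        records, columns=["trial", "step", "state", "reward", "delta", "value"]
    )
    df[["trial", "step", "state"]] = df[["trial", "step", "state"]].astype(int)
    return df


def punctate_fixed_point(
    n_states: int,
    reward: float,
    a: float = 0.15,
    kappa: float = 0.0,
    gamma: float = 1.0,
    tol: float = 1e-12,
    max_trials: int = 2_000_000,
) -> np.ndarray:
    """Steady state of the deterministic update-then-decay trial map.

    Iterates the per-trial dynamics (delta, update, decay at each step) on a
    fixed reward until the values change by less than ``tol`` (sup norm)
    across one trial.  With kappa = 0 and gamma = 1 this is ``reward`` at
    every state; with decay the profile is depressed toward the cue.
    """
    V = np.zeros(n_states)
    for _ in range(max_trials):
        prev = V.copy()
        for i in range(1, n_states + 1):
            R_i = reward if i == n_states else 0.0
            d = td_rpe(V, i, R_i, gamma)
            V[i - 1] += a * d
            V *= 1.0 - kappa
        if np.max(np.abs(V - prev)) < tol:
            return V
    raise RuntimeError("fixed-point iteration did not converge")


def steady_delta_profile(trace: pd.DataFrame, last_k: int = 1) -> pd.Series:
    """Mean delta per step over the last ``last_k`` trials of a trace."""
    last = trace["trial"].max()
    sel = trace[trace["trial"] > last - last_k]
    return sel.groupby("step")["delta"].mean()
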