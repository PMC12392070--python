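"""Hierarchical RL: coupled fast-forgetting and slow-retaining critics.

Two TD critics share the punctate state space of the cue-reward task:

* circuit M (caudate head / rostromedial SNc): large learning rate ``a_M``
  and value decay ``kappa_M``; a standard TD-RPE driven by external reward,
  ``delta_M_i = R_i + gamma V_M(S_{i+1}) - V_M(S_i)``.
* circuit L (caudate tail / caudolateral SNc): small learning rate ``a_L``
  and (by default) no decay; its RPE has **no reward term** — reinforcement
  arrives only as conditioned reinforcement, the upcoming-state value relayed
  from circuit M:

      delta_L_i = gamma (0.5 V_L(S_{i+1}) + 0.5 V_M(S_{i+1}))
                  - lambda_cur * V_L(S_i)

  (the bracketed upcoming term is dropped at the terminal state).  With
  ``lambda_cur = 1`` the negative current-value input matches the summed
  upcoming coefficients; the revised variant ``lambda_cur = 0.5`` matches
  only circuit L's own upcoming coefficient, making the effective discount
  exceed 1 in the presence of the M -> L input (value amplification toward
  the cue, hence stable habit-like retention).

Protocols chain phases: ``learning`` (rewarded trials), ``rest`` (decay only,
applied n_states x n_trials times), and ``extinction`` (trials with the
reward term zeroed), with values carried continuously across phases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tasks import TaskSpec, sample_reward

__all__ = [
    "HierarchicalParams",
    "HierarchicalState",
    "circuit_m_rpe",
    "circuit_l_rpe",
    "run_hierarchical",
    "HierarchicalResult",
]


@dataclass(frozen=True)
class HierarchicalParams:
    a_M: float = 0.25
    a_L: float = 0.025
    kappa_M: float = 0.01
    kappa_L: float = 0.0
    lambda_cur: float = 1.0  # coefficient of the -V_L(S_i) term in delta_L
    gamma: float = 1.0


@dataclass
class HierarchicalState:
    V_M: np.ndarray
    V_L: np.ndarray
    params: HierarchicalParams = field(default_factory=HierarchicalParams)


def circuit_m_rpe(state: HierarchicalState, i: int, R_i: float) -> float:
    """Standard TD-RPE on circuit M's values (successor term dropped at i = n)."""
    V = state.V_M
    n = len(V)
    if not 1 <= i <= n:
        raise IndexError(f"state index {i} out of range 1..{n}")
    g = state.params.gamma
    if i == n:
        return float(R_i - V[i - 1])
    return float(R_i + g * V[i] - V[i - 1])


def circuit_l_rpe(state: HierarchicalState, i: int) -> float:
    """Conditioned-reinforcement RPE of circuit L (no reward term).

    ``gamma (0.5 V_L(S_{i+1}) + 0.5 V_M(S_{i+1})) - lambda_cur V_L(S_i)``;
    at the terminal state only the negative current-value term remains.
    """
    n = len(state.V_L)
    if not 1 <= i <= n:
        raise IndexError(f"state index {i} out of range 1..{n}")
    p = state.params
    cur = p.lambda_cur * state.V_L[i - 1]
    if i == n:
        return float(-cur)
    upcoming = 0.5 * state.V_L[i] + 0.5 * state.V_M[i]
    return float(p.gamma * upcoming - cur)


@dataclass
class HierarchicalResult:
    trace: pd.DataFrame  # (phase, phase_index, trial, step, delta_M, delta_L, V_M, V_L)
    phase_end_values: list[tuple[str, np.ndarray, np.ndarray]]  # (phase, V_M, V_L)
    final_state: HierarchicalState

    def cue_response(self, phase: str, trial: int) -> tuple[float, float]:
        """(circuit M, circuit L) cue responses at a given trial of a phase."""
        sel = self.trace[
            (self.trace["phase"] == phase)
            & (self.trace["trial"] == trial)
            & (self.trace["step"] == 0)
        ]
        row = sel.iloc[0]
        return float(row["delta_M"]), float(row["delta_L"])


def run_hierarchical(
    phases=(("learning", 200), ("rest", 200), ("extinction", 200)),
    params: HierarchicalParams | None = None,
    spec: TaskSpec | None = None,
    rng: np.random.Generator | None = None,
) -> HierarchicalResult:
    """Run the coupled two-circuit agent through an ordered list of phases.

    Learning and extinction trials run the shared within-trial loop: both
    circuits compute their RPE from pre-update values (synchronously), both
    update, then both decay with their own rates.  Extinction is identical to
    learning except the reward term is zero.  Rest applies only decay,
    ``n_states * n_trials`` times, recorded as one row per virtual trial.

    Cue responses are recorded at step 0 of each trial from pre-trial values:
    ``gamma V_M(S_1)`` for circuit M and
    ``gamma (0.5 V_L(S_1) + 0.5 V_M(S_1))`` for circuit L (the same implicit
    zero-value pre-cue state convention as the tabular module, applied to
    each circuit's own value composite).
    """
    if params is None:
        params = HierarchicalParams()
    if spec is None:
        spec = TaskSpec(5, ((1.0, 1.0),), 1, params.gamma)
    if rng is None:
        rng = np.random.default_rng(0)
    n = spec.n_states
    g = params.gamma
    state = HierarchicalState(np.zeros(n), np.zeros(n), params)

    rows = []
    phase_end_values = []
    for phase_index, (phase, n_trials) in enumerate(phases):
        if phase == "rest":
            decay_m = (1.0 - params.kappa_M) ** n
            decay_l = (1.0 - params.kappa_L) ** n
            for trial in range(n_trials):
                state.V_M *= decay_m
                state.V_L *= decay_l
                rows.append(
                    (phase, phase_index, trial, 0, np.nan, np.nan,
                     state.V_M[0], state.V_L[0])
                )
        elif phase in ("learning", "extinction"):
            for trial in range(n_trials):
                r = sample_reward(spec, rng) if phase == "learning" else 0.0
                cue_m = g * state.V_M[0]
                cue_l = g * (0.5 * state.V_L[0] + 0.5 * state.V_M[0])
                rows.append(
                    (phase, phase_index, trial, 0, cue_m, cue_l,
                     state.V_M[0], state.V_L[0])
                )
                for i in range(1, n + 1):
                    R_i = r if i == n else 0.0
                    d_m = circuit_m_rpe(state, i, R_i)
                    d_l = circuit_l_rpe(state, i)
                    rows.append(
                        (phase, phase_index, trial, i, d_m, d_l,
                         state.V_M[i - 1], state.V_L[i - 1])
                    )
                    state.V_M[i - 1] += params.a_M * d_m
                    state.V_L[i - 1] += params.a_L * d_l
                    state.V_M *= 1.0 - params.kappa_M
                    state.V_L *= 1.0 - params.kappa_L
        else:
            raise ValueError(f"unknown phase: {phase!r}")
        phase_end_values.append((phase, state.V_M.copy(), state.V_L.copy()))

    trace = pd.DataFrame(
        rows,
        columns=[
            "phase", "phase_index", "trial", "step",
            "delta_M", "delta_L", "V_M", "V_L",
        ],
    )
    return HierarchicalResult(
        trace=trace, phase_end_values=phase_end_values, final_state=state
    )
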