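"""Trial-based cue-reward association task structures.

Every model in this package is simulated on the same Pavlovian task: on each
trial the agent passes deterministically through within-trial states
``S_1 .. S_n`` (cue at ``S_1``, reward at ``S_n``, nothing in between).  The
reward schedule may be deterministic (a point mass) or probabilistic (a finite
mixture of sizes).  The recurrent-network model additionally consumes a
continuous observation stream in which cue and reward are encoded by binary
observation units and trials are separated by variable inter-trial intervals
(ITIs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TaskSpec",
    "ObservationStream",
    "make_task",
    "sample_reward",
    "make_observation_stream",
    "SHORT_ITI_STEPS",
    "LONG_ITI_STEPS",
    "CUE_DURATION",
]

#: cue occupies this many consecutive time-steps; reward follows on the next.
CUE_DURATION = 4

#: admissible ITI lengths (steps strictly between reward and the next cue).
SHORT_ITI_STEPS = (4, 5, 6, 7)
LONG_ITI_STEPS = (7, 9, 11, 13)


@dataclass(frozen=True)
class TaskSpec:
    """Immutable description of a cue-reward association task.

    Parameters
    ----------
    n_states
        Number of within-trial states ``S_1 .. S_n``; the cue corresponds to
        ``S_1`` and reward is delivered at ``S_n`` only.
    reward_schedule
        Tuple of ``(size, probability)`` pairs; one size is drawn per trial.
    n_trials
        Number of trials to simulate.
    gamma
        Time discount factor in [0, 1].
    """

    n_states: int
    reward_schedule: tuple[tuple[float, float], ...]
    n_trials: int
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        probs = [p for _, p in self.reward_schedule]
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError(
                "reward_schedule probabilities must be non-negative and sum to 1"
            )

    @property
    def reward_sizes(self) -> np.ndarray:
        return np.array([s for s, _ in self.reward_schedule], dtype=float)

    @property
    def reward_probs(self) -> np.ndarray:
        return np.array([p for _, p in self.reward_schedule], dtype=float)

    @property
    def mean_reward(self) -> float:
        return float(self.reward_sizes @ self.reward_probs)

    @property
    def deterministic(self) -> bool:
        return len(self.reward_schedule) == 1

    def to_dict(self) -> dict:
        return {
            "n_states": self.n_states,
            "reward_schedule": [list(pair) for pair in self.reward_schedule],
            "n_trials": self.n_trials,
            "gamma": self.gamma,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TaskSpec":
        return cls(
            n_states=int(d["n_states"]),
            reward_schedule=tuple(
                (float(s), float(p)) for s, p in d["reward_schedule"]
            ),
            n_trials=int(d["n_trials"]),
            gamma=float(d["gamma"]),
        )


def make_task(
    n_states: int,
    reward_schedule,
    n_trials: int,
    gamma: float = 1.0,
) -> TaskSpec:
    """Construct a validated :class:`TaskSpec`.

    ``reward_schedule`` may be any iterable of ``(size, probability)`` pairs,
    e.g. ``[(1, 1.0)]`` for a fixed unit reward or ``[(1, 0.5), (3, 0.5)]``
    for an equiprobable two-point distribution.
    """
    schedule = tuple((float(s), float(p)) for s, p in reward_schedule)
    return TaskSpec(n_states, schedule, n_trials, gamma)


def sample_reward(spec: TaskSpec, rng: np.random.Generator) -> float:
    """Draw one reward size for a trial according to ``spec.reward_schedule``."""
    if spec.deterministic:
        return float(spec.reward_sizes[0])
    idx = rng.choice(len(spec.reward_schedule), p=spec.reward_probs)
    return float(spec.reward_sizes[idx])


def sample_rewards(
    spec: TaskSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized draw of ``n`` per-trial reward sizes."""
    if spec.deterministic:
        return np.full(n, spec.reward_sizes[0])
    idx = rng.choice(len(spec.reward_schedule), size=n, p=spec.reward_probs)
    return spec.reward_sizes[idx]


@dataclass(frozen=True)
class ObservationStream:
    """Continuous binary observation stream for the recurrent-network model.

    Five observation units: units 1-4 encode the cue, unit 5 the reward.  A
    *fixed* cue activates unit 1 for four consecutive steps; a *dynamic* cue
    activates units 1..4 sequentially, one step each.  Reward follows on the
    step after the last cue step.  The ITI is counted exclusively: it is the
    number of steps strictly between the reward step and the first cue step
    of the next trial (and, for the first trial, before its first cue step).
    """

    cue_type: str
    iti_kind: str
    o: np.ndarray  # (T, 5) float array of unit activities
    trial_index: np.ndarray  # (T,) trial each step belongs to (ITI -> next trial)
    cue_onsets: np.ndarray  # (n_trials,) first cue step of each trial
    reward_times: np.ndarray  # (n_trials,) reward step of each trial
    itis: np.ndarray = field(repr=False, default=None)  # (n_trials,) drawn ITIs

    @property
    def n_steps(self) -> int:
        return self.o.shape[0]

    @property
    def n_trials(self) -> int:
        return self.cue_onsets.shape[0]

    @property
    def rewards(self) -> np.ndarray:
        """Per-step reward signal r(t): the reward-unit activity."""
        return self.o[:, 4]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.o.astype(int), columns=[f"o{k}" for k in range(1, 6)]
        )
        df.insert(0, "t", np.arange(self.n_steps))
        df["trial_index"] = self.trial_index
        return df


def make_observation_stream(
    cue_type: str,
    iti_kind: str,
    n_trials: int,
    rng: np.random.Generator,
) -> ObservationStream:
    """Generate a concatenated observation stream of ``n_trials`` trials.

    Each trial consists of an ITI (drawn uniformly from the short or long
    menu), four cue steps and one reward step.  In the fixed-cue condition
    only unit 1 is cue-active; in the dynamic-cue condition unit ``k`` is
    active at the ``k``-th cue step.
    """
    if cue_type not in ("fixed", "dynamic"):
        raise ValueError(f"unknown cue_type: {cue_type!r}")
    if iti_kind not in ("short", "long"):
        raise ValueError(f"unknown iti_kind: {iti_kind!r}")

    menu = SHORT_ITI_STEPS if iti_kind == "short" else LONG_ITI_STEPS
    itis = rng.choice(menu, size=n_trials)

    trial_len = CUE_DURATION + 1
    total = int(itis.sum()) + n_trials * trial_len
    o = np.zeros((total, 5))
    trial_index = np.empty(total, dtype=int)
    cue_onsets = np.empty(n_trials, dtype=int)
    reward_times = np.empty(n_trials, dtype=int)

    t = 0
    for trial, iti in enumerate(itis):
        trial_index[t : t + iti + trial_len] = trial
        t += int(iti)  # silent ITI steps preceding this trial's cue
        cue_onsets[trial] = t
        for k in range(CUE_DURATION):
            unit = 0 if cue_type == "fixed" else k
            o[t + k, unit] = 1.0
        t += CUE_DURATION
        o[t, 4] = 1.0  # reward unit
        reward_times[trial] = t
        t += 1

    return ObservationStream(
        cue_type=cue_type,
        iti_kind=iti_kind,
        o=o,
        trial_index=trial_index,
        cue_onsets=cue_onsets,
        reward_times=reward_times,
        itis=np.asarray(itis, dtype=int),
    )
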