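"""Distributional RL with D1/D2 value pairs: integRPE and segreRPE algorithms.

Two value vectors ``V1`` (direct-pathway, D1) and ``V2`` (indirect-pathway,
D2) are learned with opposite learning-rate asymmetries for positive versus
negative TD-RPE, default quadruple ``(a1+, a1-, a2+, a2-) = (0.15, 0.05,
0.05, 0.15)``:

* **integRPE** — one unified RPE computed from the *sum* of the two values,

      delta_i = R_i + gamma (V1(S_{i+1}) + V2(S_{i+1})) - (V1(S_i) + V2(S_i))

  drives both updates.  Only the sum is anchored, so the individual values
  drift apart without bound on stochastic rewards unless value decay
  (``kappa > 0``) is applied.
* **segreRPE** — each pathway computes its own RPE from its own values only,

      delta_j_i = R_i + gamma Vj(S_{i+1}) - Vj(S_i)

  so each value converges to an expectile-like asymmetric fixed point of the
  reward distribution: the terminal value q solves
  ``a+ E[(R - q)+] = a- E[(q - R)+]``.

Value decay, when enabled, multiplies every entry of both vectors by
``(1 - kappa)`` at each within-trial time-step, as in the tabular module.

The coding analyses quantify how well the (D1, D2) pair distinguishes reward
*distributions* (cosine-similarity of fixed-minus-variable difference
vectors) and how well it encodes the reward *mean* (regression R^2 across
conditions), using many independent simulations with read-out noise added
after learning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tasks import TaskSpec, sample_rewards

__all__ = [
    "DistributionalParams",
    "integ_rpe",
    "segre_rpe",
    "asym_update",
    "decay_value_pair",
    "run_distributional",
    "run_distributional_batch",
    "DistributionalResult",
    "distribution_coding_score",
    "mean_coding_score",
    "expectile_fixed_point",
    "CODING_CONDITIONS",
]

DEFAULT_RATES = (0.15, 0.05, 0.05, 0.15)

#: reward schedules of the three coding-analysis conditions (means 0, 2, 2).
CODING_CONDITIONS = {
    "always0": ((0.0, 1.0),),
    "variable13": ((1.0, 0.5), (3.0, 0.5)),
    "always2": ((2.0, 1.0),),
}


@dataclass(frozen=True)
class DistributionalParams:
    rates: tuple[float, float, float, float] = DEFAULT_RATES
    kappa: float = 0.0
    gamma: float = 1.0


def integ_rpe(V1: np.ndarray, V2: np.ndarray, i: int, R_i: float,
              gamma: float = 1.0) -> float:
    """Unified RPE from the sum of D1 and D2 values (middle term dropped at i = n)."""
    n = len(V1)
    if not 1 <= i <= n:
        raise IndexError(f"state index {i} out of range 1..{n}")
    cur = V1[i - 1] + V2[i - 1]
    if i == n:
        return float(R_i - cur)
    return float(R_i + gamma * (V1[i] + V2[i]) - cur)


def segre_rpe(V1: np.ndarray, V2: np.ndarray, i: int, R_i: float,
              pathway: int, gamma: float = 1.0) -> float:
    """Per-pathway RPE from that pathway's values only."""
    if pathway not in (1, 2):
        raise ValueError("pathway must be 1 or 2")
    V = V1 if pathway == 1 else V2
    n = len(V)
    if not 1 <= i <= n:
        raise IndexError(f"state index {i} out of range 1..{n}")
    if i == n:
        return float(R_i - V[i - 1])
    return float(R_i + gamma * V[i] - V[i - 1])


def asym_update(V: np.ndarray, i: int, delta: float,
                a_plus: float, a_minus: float) -> np.ndarray:
    """Update entry ``i`` (1-based) with the sign-dependent learning rate."""
    out = np.array(V, dtype=float)
    a = a_plus if delta >= 0 else a_minus
    out[i - 1] += a * delta
    return out


def decay_value_pair(V1: np.ndarray, V2: np.ndarray,
                     kappa: float) -> tuple[np.ndarray, np.ndarray]:
    """Multiplicative decay of every entry of both value vectors."""
    if not 0.0 <= kappa < 1.0:
        raise ValueError("kappa must lie in [0, 1)")
    f = 1.0 - kappa
    return np.asarray(V1, dtype=float) * f, np.asarray(V2, dtype=float) * f


def expectile_fixed_point(sizes, probs, a_plus: float, a_minus: float) -> float:
    """Asymmetric fixed point q of terminal-value learning on a finite reward
    distribution: solves ``a+ E[(R-q)+] = a- E[(q-R)+]`` by bisection.

    For ``a+ = a-`` this is the mean; in general an expectile-like statistic.
    """
    sizes = np.asarray(sizes, dtype=float)
    probs = np.asarray(probs, dtype=float)

    def drift(q):
        d = sizes - q
        return float(probs @ np.where(d >= 0, a_plus * d, a_minus * d))

    lo, hi = float(sizes.min()), float(sizes.max())
    if lo == hi:
        return lo
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if drift(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass
class DistributionalResult:
    algorithm: str
    trace: pd.DataFrame  # (trial, step, reward, delta, delta1, delta2, V1, V2)
    snapshots: dict  # trial -> (V1 copy, V2 copy) taken *after* that trial
    final_V1: np.ndarray
    final_V2: np.ndarray


def run_distributional(
    algorithm: str,
    spec: TaskSpec,
    kappa: float = 0.0,
    rates: tuple[float, float, float, float] = DEFAULT_RATES,
    rng: np.random.Generator | None = None,
    snapshot_trials: tuple[int, ...] = (),
) -> DistributionalResult:
    """Single simulation of the integRPE or segreRPE algorithm.

    The trial loop mirrors the tabular module: per state, compute the RPE(s)
    from pre-update values, update (each pathway with its sign-dependent
    rate), then decay both vectors.  ``snapshot_trials`` are 1-based trial
    counts after which (V1, V2) copies are stored.

    Trace columns: ``delta`` is the unified RPE for integRPE and NaN for
    segreRPE; ``delta1``/``delta2`` are the per-pathway RPEs (equal to the
    unified one for integRPE).
    """
    if algorithm not in ("integRPE", "segreRPE"):
        raise ValueError(f"unknown algorithm: {algorithm!r}")
    if rng is None:
        rng = np.random.default_rng(0)
    a1p, a1m, a2p, a2m = rates
    n = spec.n_states
    g = spec.gamma
    V1 = np.zeros(n)
    V2 = np.zeros(n)
    rewards = sample_rewards(spec, spec.n_trials, rng)

    rows = []
    snapshots = {}
    for trial in range(spec.n_trials):
        r = rewards[trial]
        for i in range(1, n + 1):
            R_i = r if i == n else 0.0
            if algorithm == "integRPE":
                d = integ_rpe(V1, V2, i, R_i, g)
                d1 = d2 = d
                V1[i - 1] += (a1p if d >= 0 else a1m) * d
                V2[i - 1] += (a2p if d >= 0 else a2m) * d
                rows.append((trial, i, r, d, d1, d2, V1[i - 1], V2[i - 1]))
            else:
                d1 = segre_rpe(V1, V2, i, R_i, 1, g)
                d2 = segre_rpe(V1, V2, i, R_i, 2, g)
                V1[i - 1] += (a1p if d1 >= 0 else a1m) * d1
                V2[i - 1] += (a2p if d2 >= 0 else a2m) * d2
                rows.append((trial, i, r, np.nan, d1, d2, V1[i - 1], V2[i - 1]))
            V1 *= 1.0 - kappa
            V2 *= 1.0 - kappa
        if trial + 1 in snapshot_trials:
            snapshots[trial + 1] = (V1.copy(), V2.copy())

    trace = pd.DataFrame(
        rows,
        columns=["trial", "step", "reward", "delta", "delta1", "delta2", "V1", "V2"],
    )
    return DistributionalResult(
        algorithm=algorithm, trace=trace, snapshots=snapshots,
        final_V1=V1, final_V2=V2,
    )


def run_distributional_batch(
    algorithm: str,
    spec: TaskSpec,
    n_sims: int,
    kappa: float = 0.0,
    rates: tuple[float, float, float, float] = DEFAULT_RATES,
    rng: np.random.Generator | None = None,
    snapshot_trials: tuple[int, ...] = (),
) -> dict:
    """Vectorized batch of independent simulations (stacked on axis 0).

    Returns a dict with ``V1``/``V2`` of shape (n_sims, n_states) after the
    last trial, per-trial terminal-state values ``terminal_V1``/``terminal_V2``
    of shape (n_sims, n_trials), realized ``rewards`` (n_sims, n_trials),
    last-trial per-step RPEs ``last_delta1``/``last_delta2`` (n_sims,
    n_states), and ``snapshots`` mapping trial -> (V1, V2) arrays.
    """
    if algorithm not in ("integRPE", "segreRPE"):
        raise ValueError(f"unknown algorithm: {algorithm!r}")
    if rng is None:
        rng = np.random.default_rng(0)
    a1p, a1m, a2p, a2m = rates
    n = spec.n_states
    g = spec.gamma
    V1 = np.zeros((n_sims, n))
    V2 = np.zeros((n_sims, n))
    rewards = sample_rewards(spec, n_sims * spec.n_trials, rng).reshape(
        n_sims, spec.n_trials
    )
    terminal_V1 = np.empty((n_sims, spec.n_trials))
    terminal_V2 = np.empty((n_sims, spec.n_trials))
    last_d1 = np.empty((n_sims, n))
    last_d2 = np.empty((n_sims, n))
    snapshots = {}
    decay = 1.0 - kappa

    for trial in range(spec.n_trials):
        r = rewards[:, trial]
        for i in range(1, n + 1):
            R_i = r if i == n else np.zeros(n_sims)
            if algorithm == "integRPE":
                cur = V1[:, i - 1] + V2[:, i - 1]
                if i == n:
                    d = R_i - cur
                else:
                    d = R_i + g * (V1[:, i] + V2[:, i]) - cur
                d1 = d2 = d
            else:
                if i == n:
                    d1 = R_i - V1[:, i - 1]
                    d2 = R_i - V2[:, i - 1]
                else:
                    d1 = R_i + g * V1[:, i] - V1[:, i - 1]
                    d2 = R_i + g * V2[:, i] - V2[:, i - 1]
            V1[:, i - 1] += np.where(d1 >= 0, a1p, a1m) * d1
            V2[:, i - 1] += np.where(d2 >= 0, a2p, a2m) * d2
            if kappa:
                V1 *= decay
                V2 *= decay
            if trial == spec.n_trials - 1:
                last_d1[:, i - 1] = d1
                last_d2[:, i - 1] = d2
        terminal_V1[:, trial] = V1[:, n - 1]
        terminal_V2[:, trial] = V2[:, n - 1]
        if trial + 1 in snapshot_trials:
            snapshots[trial + 1] = (V1.copy(), V2.copy())

    return {
        "V1": V1,
        "V2": V2,
        "terminal_V1": terminal_V1,
        "terminal_V2": terminal_V2,
        "rewards": rewards,
        "last_delta1": last_d1,
        "last_delta2": last_d2,
        "snapshots": snapshots,
    }


def _pairwise_cosine_stats(U: np.ndarray) -> tuple[float, float, int]:
    """Mean, SD and count over all unordered pairs of cosine similarities of
    the rows of ``U`` (rows assumed already unit-normalised)."""
    N = U.shape[0]
    C = U @ U.T
    iu = np.triu_indices(N, k=1)
    vals = C[iu]
    return float(vals.mean()), float(vals.std()), vals.size


def distribution_coding_score(
    fixed_values: dict,
    variable_values: dict,
    noise_sd: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Strength of reward-distribution coding per time-step.

    ``fixed_values`` and ``variable_values`` each hold paired simulation
    outputs with keys ``"V1"``/``"V2"`` of shape (n_sims, n_steps) — the
    learned values of the always-2 ("fixed") and {1, 3} ("variable")
    conditions, paired by simulation index.  Gaussian read-out noise of SD
    ``noise_sd`` is added to every value; for each time-step the n_sims
    difference vectors ``(D1_fix - D1_var, D2_fix - D2_var)`` are formed and
    the mean +/- SD of the cosine similarity over all unordered pairs is
    returned, with columns (step, cos_mean, cos_sd, n_pairs, n_excluded)
    where ``n_excluded`` counts zero-length difference vectors.
    """
    V1f = fixed_values["V1"] + rng.normal(0.0, noise_sd, fixed_values["V1"].shape)
    V2f = fixed_values["V2"] + rng.normal(0.0, noise_sd, fixed_values["V2"].shape)
    V1v = variable_values["V1"] + rng.normal(0.0, noise_sd, variable_values["V1"].shape)
    V2v = variable_values["V2"] + rng.normal(0.0, noise_sd, variable_values["V2"].shape)

    n_steps = V1f.shape[1]
    rows = []
    for s in range(n_steps):
        D = np.column_stack([V1f[:, s] - V1v[:, s], V2f[:, s] - V2v[:, s]])
        norms = np.linalg.norm(D, axis=1)
        keep = norms > 0
        U = D[keep] / norms[keep, None]
        mean, sd, n_pairs = _pairwise_cosine_stats(U)
        rows.append((s + 1, mean, sd, n_pairs, int((~keep).sum())))
    return pd.DataFrame(
        rows, columns=["step", "cos_mean", "cos_sd", "n_pairs", "n_excluded"]
    )


def mean_coding_score(
    condition_values: dict,
    reward_means: dict,
    noise_sd: float,
    rng: np.random.Generator,
    estimator: str = "univariate",
) -> pd.DataFrame:
    """Strength of reward-mean coding per time-step.

    ``condition_values`` maps condition name -> batch output with
    ``"V1"``/``"V2"`` arrays (n_sims, n_steps), paired by simulation index
    across conditions; ``reward_means`` maps condition name -> mean reward.
    Gaussian noise is added, then D1 and D2 values are z-normalised across
    the conditions separately for each simulation and time-step.  Per
    time-step the default estimator averages the two squared Pearson
    correlations of the reward mean with the normalised D1 and D2 values
    pooled over simulations x conditions; ``estimator="multiple"`` instead
    returns the single multiple-regression R^2 on both predictors jointly.
    The per-pathway average is the default because the terminal-state D2
    value of the decaying unified-RPE algorithm orders the equal-mean
    conditions differently from the reward mean, which only a per-pathway
    correlation registers (the joint regression can re-weight it away).
    """
    if estimator not in ("multiple", "univariate"):
        raise ValueError("estimator must be 'multiple' or 'univariate'")
    names = list(condition_values)
    noisy1 = {}
    noisy2 = {}
    for name in names:
        v = condition_values[name]
        noisy1[name] = v["V1"] + rng.normal(0.0, noise_sd, v["V1"].shape)
        noisy2[name] = v["V2"] + rng.normal(0.0, noise_sd, v["V2"].shape)

    # stack to (n_conditions, n_sims, n_steps) and z-normalise across axis 0
    A1 = np.stack([noisy1[n] for n in names])
    A2 = np.stack([noisy2[n] for n in names])

    def znorm(A):
        mu = A.mean(axis=0, keepdims=True)
        sd = A.std(axis=0, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            Z = (A - mu) / sd
        return np.where(sd > 0, Z, np.nan)

    Z1 = znorm(A1)
    Z2 = znorm(A2)
    y_cond = np.array([reward_means[n] for n in names], dtype=float)

    n_cond, n_sims, n_steps = Z1.shape
    y = np.repeat(y_cond, n_sims)
    rows = []
    for s in range(n_steps):
        p1 = Z1[:, :, s].ravel()
        p2 = Z2[:, :, s].ravel()
        keep = np.isfinite(p1) & np.isfinite(p2)
        yy = y[keep]
        ss_tot = float(((yy - yy.mean()) ** 2).sum())
        if estimator == "multiple":
            Xd = np.column_stack([np.ones(keep.sum()), p1[keep], p2[keep]])
            beta, *_ = np.linalg.lstsq(Xd, yy, rcond=None)
            resid = yy - Xd @ beta
            r2 = 1.0 - float((resid ** 2).sum()) / ss_tot
        else:
            r2s = []
            for p in (p1[keep], p2[keep]):
                c = np.corrcoef(p, yy)[0, 1]
                r2s.append(c * c)
            r2 = float(np.mean(r2s))
        rows.append((s + 1, r2, int((~keep).sum())))
    return pd.DataFrame(rows, columns=["step", "r2", "n_dropped"])
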