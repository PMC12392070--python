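"""Distributional RL with D1/D2 value pairs: what each algorithm encodes.

Compares the unified-RPE algorithm (integRPE, with value decay 0.01) and the
segregated-RPE algorithm (segreRPE, no decay) on probabilistic {1, 3} and
deterministic (always 2) reward tasks, then quantifies distribution coding
(pairwise cosine similarity of condition-difference vectors) and mean coding
(per-pathway R^2) with read-out noise SD 0.05.
"""

import numpy as np

from decayrl.distributional import (
    CODING_CONDITIONS,
    distribution_coding_score,
    expectile_fixed_point,
    mean_coding_score,
    run_distributional_batch,
)
from decayrl.tasks import make_task

rng = np.random.default_rng(0)
spec13 = make_task(5, [(1.0, 0.5), (3.0, 0.5)], 2000)

segre = run_distributional_batch("segreRPE", spec13, 100, rng=rng)
print("segreRPE terminal values on the {1,3} task (long-run means):")
print(f"  D1 {segre['terminal_V1'][:, 1000:].mean():.3f}  "
      f"(asymmetric fixed point {expectile_fixed_point([1, 3], [.5, .5], 0.15, 0.05):.2f})")
print(f"  D2 {segre['terminal_V2'][:, 1000:].mean():.3f}  "
      f"(asymmetric fixed point {expectile_fixed_point([1, 3], [.5, .5], 0.05, 0.15):.2f})")

integ = run_distributional_batch("integRPE", spec13, 100, rng=rng,
                                 snapshot_trials=(200, 2000))
for t, (V1, V2) in integ["snapshots"].items():
    print(f"integRPE (no decay) trial {t}: max|D1| {np.abs(V1).max():.1f}, "
          f"max|D2| {np.abs(V2).max():.1f}, D1+D2 at reward "
          f"{(V1 + V2)[:, 4].mean():.2f}")

specs = {n: make_task(5, s, 200) for n, s in CODING_CONDITIONS.items()}
batches = {
    alg: {n: run_distributional_batch(alg, sp, 1000, kappa=k, rng=rng)
          for n, sp in specs.items()}
    for alg, k in (("integRPE", 0.01), ("segreRPE", 0.0))
}
means = {"always0": 0.0, "variable13": 2.0, "always2": 2.0}
print("\nper-time-step scores (steps 1..5, noise SD 0.05):")
for alg in batches:
    dc = distribution_coding_score(batches[alg]["always2"],
                                   batches[alg]["variable13"], 0.05, rng)
    mc = mean_coding_score(batches[alg], means, 0.05, rng)
    print(f"  {alg}: distribution {np.round(dc['cos_mean'].values, 3)}")
    print(f"  {alg}: mean coding  {np.round(mc['r2'].values, 3)}")

print(
    "\nThe segregated algorithm's D1/D2 pair converges to expectile-like\n"
    "statistics and so separates reward distributions at every time-step\n"
    "(high cosine scores); the unified algorithm anchors only the SUM of\n"
    "the values (individual values grow without bound unless decay is\n"
    "added) and distinguishes distributions only at the reward step, but\n"
    "its decay-induced value ramp progressively improves reward-mean\n"
    "coding toward the reward."
)
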