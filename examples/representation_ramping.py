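"""RPE ramping under weight decay depends on the state representation.

Linear-feature TD (a+ = 0.15, a- = 0.075, weight decay 0.01) on the same
task, with sparse / dense random features and successor (SR) / predecessor
(PR) representations.  Prints the steady per-step RPE for each.
"""

import numpy as np

from decayrl.feature_td import make_features, run_feature_td
from decayrl.tasks import make_task

spec = make_task(5, [(1.0, 1.0)], 200, gamma=1.0)
master = np.random.default_rng(7)

for kind in ("sparse", "dense", "SR", "PR"):
    if kind in ("sparse", "dense"):
        acc = []
        for _ in range(100):
            r = np.random.default_rng(master.integers(2**31))
            feats = make_features(kind, 5, 100, 10, rng=r)
            tr = run_feature_td(spec, feats, kappa=0.01, rng=r)
            acc.append(tr[tr["trial"] == 199]["delta"].values)
        prof = np.mean(acc, axis=0)
        note = "(mean of 100 feature draws)"
    else:
        feats = make_features(kind, 5, gamma=1.0)
        tr = run_feature_td(spec, feats, kappa=0.01)
        prof = tr[tr["trial"] == 199]["delta"].values
        note = ""
    print(f"{kind:6s} RPE (cue, S1..S5): {np.round(prof, 3)} {note}")

print(
    "\nIntermediate-state RPE (entries 3-5) orders sparse > dense > SR ~ 0:\n"
    "the more feature vectors of successive states overlap, the less decay\n"
    "can produce a ramp.  PR instead ramps DOWN - overlap with PAST states\n"
    "spreads value backwards, so temporal order matters, not overlap alone."
)
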