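"""The online value-RNN: value-weight decay makes RPE shape depend on cue
type and inter-trial-interval length.

Trains the 40-unit oVRNN (gamma = 0.8) for 1,000 trials per condition and
prints the trial-aligned RPE profile (cue step first, reward step last)
averaged over the last 100 trials and 20 seeds per condition.
"""

import numpy as np

from decayrl.ovrnn import has_cue_peak, run_ovrnn

N_SEEDS = 20

for dr in (0.0, 0.001):
    print(f"\nvalue-weight decay dr = {dr}")
    for cue in ("fixed", "dynamic"):
        for iti in ("short", "long"):
            profs = []
            for s in range(N_SEEDS):
                res = run_ovrnn(cue, iti, dr=dr, n_trials=1000,
                                rng=np.random.default_rng(100 + s))
                profs.append(res.mean_profile(100)["delta"].values)
            prof = np.mean(profs, axis=0)
            tag = "cue peak" if has_cue_peak(prof) else "increasing"
            print(f"  {cue:7s} cue, {iti:5s} ITI: {np.round(prof, 3)} -> {tag}")

print(
    "\nWithout decay every condition shows a prominent cue peak.  With decay\n"
    "(0.001/step) the cue peak survives only when the cue is fixed or the\n"
    "ITI is long; with a dynamic cue and short ITI the profile instead\n"
    "increases toward reward - matching condition-dependent dopamine ramps."
)
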