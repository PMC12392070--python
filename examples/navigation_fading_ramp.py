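"""Dopamine-like ramps fade as a successor representation is learned.

Reward navigation on a 5-state linear track: the representation starts
punctate and is shaped toward the SR online (a_SR = 0.001) while value
weights learn with decay (0.01).  Prints the session-averaged RPE over the
post-start..pre-goal states for each of the nine 40-trial sessions.
"""

import numpy as np

from decayrl.feature_td import make_features, run_navigation

nav = run_navigation(reward_size=1.0, rng=np.random.default_rng(0))
sm = nav.session_mean_delta()
sr = make_features("SR", 5, gamma=1.0).X

print("session   RPE(S2)  RPE(S3)  RPE(S4)   |X - SR|_F")
for s, row in sm.iterrows():
    d = np.linalg.norm(nav.session_features[s] - sr)
    print(f"   {s + 1}      {row[2]:.4f}   {row[3]:.4f}   {row[4]:.4f}     {d:.3f}")

print(
    "\nThe ramp amplitude shrinks monotonically across sessions while the\n"
    "feature matrix approaches the exact successor matrix (last column):\n"
    "decay-induced ramping is a signature of a still-punctate code and\n"
    "fades as predictive structure is absorbed into the representation."
)
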