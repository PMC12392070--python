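# decayrl

Simulators for temporal-difference (TD) learning models of the
dopamine–striatum system in which learned values **decay** over time, and for
the reward-prediction-error (RPE) patterns this produces.

Midbrain dopamine signals are heterogeneous: some populations show an abrupt,
cue-locked response, others a slow ramp toward reward; some retain learned
responses for months, others forget within a day; some appear to encode the
full reward distribution, others mainly its mean.  `decayrl` implements one
family of models in which a single mechanism — multiplicative decay of
learned values or value weights, modelling passive loss of dopamine-dependent
plasticity — interacts with the *state representation* and the *circuit
architecture* to generate all of these patterns.  It is intended for
computational neuroscientists who want to regenerate, probe or extend these
simulations.

## Models

All models share a Pavlovian cue–reward task: within a trial the agent
traverses states `S_1 … S_n` (cue at `S_1`, reward at `S_n`) and computes the
TD RPE

```
δ_i = R_i + γ V(S_{i+1}) − V(S_i)        (the γ term is dropped at i = n)
```

- **`tabular_td`** — punctate (one-state-per-timing) TD(0) with update
  `V(S_i) ← V(S_i) + a δ_i` and per-time-step decay `V ← (1 − κ) V`.
  Decay produces a ramping RPE; temporal discounting (γ < 1) does not.
- **`feature_td`** — linear function approximation `V(S_i) = w·x_i − w0·Σx_i`
  with non-negative weights, asymmetric learning rates (a₊ > a₋), and weight
  decay toward the initial baseline `w0`.  Feature sets: sparse / dense
  random vectors, successor (SR) and predecessor (PR) representations, and an
  SR learned online through TD learning of the features themselves
  (navigation with fading ramps).
- **`ovrnn`** — an online value-RNN: a 40-unit sigmoidal RNN and its value
  readout are trained simultaneously by the same scalar RPE, with random
  feedback instead of backpropagation, continuously across trials and
  inter-trial intervals.  Value-weight decay makes the trained RPE profile
  depend on cue type (fixed vs dynamic) and ITI length.
- **`hierarchical`** — two coupled critics: circuit M (fast learning, decay)
  drives circuit L (slow, decay-free) purely through conditioned
  reinforcement; L's RPE contains no reward term.  Reproduces fast
  forgetting alongside stable long-term value memory.
- **`distributional`** — D1/D2 value pairs with opposite learning-rate
  asymmetries, updated either from one **unified** RPE computed from the sum
  of the values (`integRPE`, needs decay to stay bounded) or from
  **segregated** per-pathway RPEs (`segreRPE`, converges to expectile-like
  fixed points), plus cosine-similarity distribution-coding and R²
  mean-coding analyses.
- **`experiments` / `decayrl` CLI** — configuration-driven reproduction of
  each protocol as long-format CSV tables with a JSON sidecar.

## Worked example

```
$ python examples/punctate_ramping.py
no decay, no discounting (k=0, g=1)
  RPE  (cue, S1..S5): [1. 0. 0. 0. 0. 0.]
  value (S1..S5):     [1. 1. 1. 1. 1.]
value decay (k=0.01, g=1)
  RPE  (cue, S1..S5): [0.238 0.082 0.109 0.145 0.192 0.256]
  value (S1..S5):     [0.238 0.316 0.421 0.56  0.744]
temporal discounting (k=0, g=0.75)
  RPE  (cue, S1..S5): [0.237 0.    0.    0.    0.    0.   ]
  value (S1..S5):     [0.316 0.422 0.562 0.75  1.   ]
```

After 200 trials without decay, the RPE has collapsed onto the cue (first
entry, the cue response `γV(S_1)`) and every state's value equals the reward.
With decay rate κ = 0.01 the steady RPE instead *ramps* from 0.11 to 0.26
toward reward while the cue response shrinks to 0.24.  Temporal discounting
(γ = 0.75) mimics the shrunken cue response and the ramping value profile
(0.32 … 1.0 = γ^(5−i)) but leaves the off-cue RPE flat — so a ramping RPE
specifically indicates decay-like forgetting, not discounting.

The other scripts in `examples/` walk through one capability each:
representation-dependent ramping, fading navigation ramps, the RNN cue/ITI
contrast, hierarchical retention, and distributional coding.

Figure-level protocols can also be run from the shell, e.g.:

```
decayrl fig3 --seed 1 --out out_fig3        # hierarchical model tables
decayrl run my_config.yaml --out out        # any serialized configuration
```

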