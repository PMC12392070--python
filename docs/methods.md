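# Methods

This note documents the models implemented in `decayrl`, the conventions and
numerical choices behind them, and what the simulations do and do not show.

## Task

All simulators share a trace-conditioning abstraction: a trial is a
deterministic pass through `n` within-trial states (`n = 5` by default; the
cue is `S_1`, reward is delivered only at `S_n`).  Reward is a point mass or
a finite mixture (`TaskSpec.reward_schedule`); the protocols used here are
always-1, always-2, {1, 3}, {0, 4} and {0.5, 1.5} (equiprobable).  Trials are
independent episodes for every model except the RNN: no TD update spans the
terminal-state → next-trial boundary.  All randomness flows through a
caller-supplied `numpy.random.Generator`; there is no global RNG state, and
every run is bit-reproducible from its seed.

For the RNN the task is instead a continuous binary observation stream with
five units: four cue units (a *fixed* cue holds unit 1 active for four steps;
a *dynamic* cue activates units 1–4 sequentially) and one reward unit on the
following step.  The inter-trial interval is counted exclusively — the number
of silent steps strictly between the reward step and the next first cue step
— and is drawn uniformly from {4, 5, 6, 7} (short) or {7, 9, 11, 13} (long).

## Tabular TD with value decay

Per time-step: compute `δ_i = R_i + γV(S_{i+1}) − V(S_i)` (γ-term dropped at
the terminal state), update the visited state `V(S_i) += a δ_i`, then decay
*all* values `V ← (1 − κ)V`.  The operation order (RPE → update → decay) is
fixed; decay applies only during task trials.  Defaults: `a = 0.15`,
`κ ∈ {0, 0.01, 0.02}`, `γ = 1` (0.75 in the discounting contrast).

**Cue-response convention.** The δ formula alone produces no steady-state
transient at `S_1`, yet a phasic cue response is the defining experimental
feature.  We model an implicit pre-cue state with permanently zero,
never-updated value, so the reported cue response is `γ·V(S_1)` evaluated
from pre-trial values; it is recorded as step 0 of each trial.  At γ = 1
this equals `V(S_1)`; a `cue_response="raw"` switch is kept for the γ < 1
case, where the two readings differ by the factor γ.

**Steady state.** Traces record the pre-update δ at each step; "steady"
profiles are taken from the final trial (configurable to an average of the
last K trials).  The deterministic update-then-decay map contracts to a
unique fixed point; `punctate_fixed_point` iterates it to tolerance and the
tests compare long runs against independently coded solvers to 1e-8.

## Linear-feature TD

`V(S_i) = w·x_i − w0·Σ_j x_{i,j}` with `w` initialised to the all-`w0`
vector (`w0 = 0.5`), so initial values are exactly zero and effective
weights can be negative although stored weights are clamped non-negative.
The update is `w ← max(0, w + a_f δ x_i/‖x_i‖²)` with `a_f = a₊ = 0.15` for
δ ≥ 0 and `a₋ = 0.075` otherwise; weight decay is two-sided toward the
baseline, `w_j ← w0 + (1 − κ)(w_j − w0)`.  The norm division matters for the
SR/PR features, which are not unit norm.

Representations: *sparse* (10 of 100 entries per state, chosen independently
across states, uniform [0, 1] values, row normalised to 1), *dense* (all 100
entries uniform, normalised), *SR* (`x_{i,j} = γ^(j−i)` for j ≥ i) and *PR*
(`x_{i,j} = γ^(i−j)` for j ≤ i), both built with their own γ = 1 regardless
of the value-learning γ.  Sparse/dense protocols draw fresh features per
repetition and report mean ± SD over 100 repetitions.

**Navigation with a learned SR.** The feature matrix starts as the identity
(punctate) and each visited state's row is updated with the feature TD error
`δ_SR_i = I_i + γx_{i+1} − x_i` at rate `a_SR = 0.001` (terminal row fixed at
`I_n` by construction), alongside value-weight learning with κ = 0.01, for
360 trials split into nine 40-trial sessions.  The headline trace is the
session-averaged RPE over `S_2 … S_4` ("post-start" to "pre-goal"); the
endpoints remain in the raw trace.  Within a time-step the feature update
precedes the value computation by default; the opposite interleaving is
available (`order="value_first"`) and differs by < 1e-3 at these rates.

## Online value-RNN

40 sigmoidal units, `x(t+1) = f(Ax(t) + Bo(t))`; value `v(t) = wᵀx(t)`;
`δ(t) = r(t) + γv(t+1) − v(t)` with γ = 0.8.  Readout update
`w ← max(0, w + a_value δ(t) x(t))` with `a_value = 0.1/(40/12) = 0.03`,
followed by per-step decay toward **zero** `w ← (1 − dr)w` (`dr` 0 or 0.001)
— unlike the feature model, where decay is toward the baseline.  The
recurrent/feedforward update uses fixed random feedback gains `c_i ∈ [0, 1]`
and a monotonic-plus-saturation postsynaptic factor (`x(1−x)` for x ≤ 0.5,
0.25 above; continuous at the branch point), applied to the previous step's
presynaptic activities with `a_RNN = 0.1`.  `A`, `B` start standard normal,
`x` and `c` uniform [0, 1], `w` at zero.  Learning is continuous across
trials and ITIs, so value-weight decay also runs during ITI steps.

Because `δ(t)` needs `v(t+1)`, all updates for time t are applied after
stepping to t+1.  The per-step loop is compiled with numba; a pure-NumPy
reference path built from the unit operations is retained and tested
equal to machine precision.

**Protocol length.** The number of trials per simulation is not pinned by
the protocols this package reproduces; the default is 1,000 trials with
profiles averaged over the last 100, which is well past the representation-
learning transient at `a_RNN = 0.1`.  Both are configurable.

**Cue-peak statistic.** A condition "shows a cue peak" if the trial-aligned
mean δ is maximal at the cue step *over the cue-to-pre-reward span*.  The
reward step is excluded because with weight decay every condition carries a
sustained positive reward response; the phenomenon of interest is whether
the profile leading up to reward is cue-dominated or increasing.  Per-seed,
this is a noisy binary readout; condition contrasts are therefore stated as
majorities across 100 seeds.

## Hierarchical two-circuit model

Circuit M is a standard tabular TD critic (`a_M = 0.25`, `κ_M = 0.01`);
circuit L (`a_L = 0.025`, `κ_L = 0`) receives no reward input — its RPE is
`δ_L = γ(0.5V_L(S_{i+1}) + 0.5V_M(S_{i+1})) − λ_cur V_L(S_i)`, conditioned
reinforcement relayed from M.  With `λ_cur = 1` the negative current-value
coefficient matches the summed upcoming coefficients; the revised variant
`λ_cur = 0.5` matches only L's own upcoming coefficient, making delayed
reward *amplified* in circuit L (values ramp backward toward the cue) and
softening the negative extinction transient.  Within a time-step both
circuits compute their RPEs from pre-update values, then both update, then
both decay — the circuits are synchronous; at these learning rates the
cross-circuit ordering is second-order.  Protocols chain learning (200
trials), rest (decay only, applied exactly `n_states × n_trials` times) and
extinction (reward term zeroed), with values carried continuously; during
extinction circuit L's RPE uses the concurrently decaying `V_M`.  Parameter
variants (halved rates, `κ_L = 0.001` for a common learning/decay ratio of
25, halved rest/extinction) are configuration presets.

## Distributional RL

Two value vectors with learning-rate quadruple `(a₁₊, a₁₋, a₂₊, a₂₋) =
(0.15, 0.05, 0.05, 0.15)`.  `integRPE` computes one δ from `V₁ + V₂` and
feeds it to both pathways with their own sign-dependent rates; only the sum
is anchored, so on stochastic rewards the individual values drift apart
without bound unless decay (κ = 0.01) is applied.  `segreRPE` computes each
pathway's δ from its own values; terminal values converge to the asymmetric
fixed point `q` solving `a₊E[(R − q)⁺] = a₋E[(q − R)⁺]` — an expectile-like
statistic (2.5 and 1.5 on the {1, 3} task), computed independently in
`expectile_fixed_point` by bisection.  Decay is harmful here: it breaks the
common fixed point on deterministic rewards.  D2 values are stored and
reported in the same sign convention as D1 (real indirect-pathway neurons
presumably encode them sign-reversed; that read-out stage is not modelled).

**Coding analyses.** 1,000 independent simulations per condition (always-0,
{1, 3}, always-2; 200 trials each — the snapshot trial is not pinned by the
source protocols, and 200 trials is past the learning transient for both
algorithms), paired across conditions by simulation index.  Gaussian
read-out noise (SD 0.05 or 0.07) is added to the learned values after
learning — it never feeds back.  *Distribution coding* per time-step: the
1,000 fixed-minus-variable difference vectors in the (D1, D2) plane, mean ±
SD of cosine similarity over all 1,000·999/2 = 499,500 unordered pairs
(zero-length vectors are excluded and counted).  *Mean coding* per
time-step: D1 and D2 values are z-normalised across the three conditions
separately per simulation, then the squared Pearson correlation of the
reward mean (0, 2, 2) with each normalised pathway is computed over
simulations × conditions and the two are averaged.  The per-pathway average
is the default because the terminal-state D2 value of the decaying
unified-RPE algorithm orders the equal-mean conditions differently from the
reward mean; a joint multiple regression can re-weight that pattern away and
would hide the terminal-step collapse this analysis is designed to expose.
A `estimator="multiple"` flag provides the joint-regression variant.

## Numerical and testing choices

- Problem sizes: tests and the acceptance script use the protocol sizes
  directly (200–2,000 trials, 100 repetitions or seeds, 1,000 coding
  simulations); the full suite runs in well under a minute on one core plus
  one-off numba compilation.
- Degenerate inputs: `n = 1` collapses cue and reward onto one state and is
  supported; reward schedules must sum to 1; decay rates must lie in [0, 1);
  zero feature vectors are rejected.
- Ties: a zero RPE uses the positive-branch learning rate (δ ≥ 0), which is
  inert anyway; the RNN plasticity factor is continuous at activity 0.5.
- Fixed points are verified against independently coded
  iterate-to-convergence solvers (tolerance 1e-8) rather than against the
  runner itself.

## What the synthetic task does and does not show

The generator reproduces the *structure* of trace-conditioning and
navigation protocols — discrete time, deterministic state progression, point
or two-point reward distributions — not their sensory richness: there is no
stimulus generalisation, no variable cue–reward delay (outside the RNN's ITI
manipulation), no action selection, and no within-state timing noise.
Passing tests therefore show that the *models* behave as described under the
stated conditions; they do not certify quantitative fits to recorded neural
data, which this package deliberately does not attempt.  Known limitations:
single-unit D1/D2 populations (no graded asymmetry spectrum), no
eligibility traces or TD(λ), and the RNN analyses cover the random-feedback
variant only, not backprop-through-time.
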