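# Methods

## The task

The two-stage Markov decision task separates habitual (model-free) from
goal-directed (model-based) choice. Each trial begins in a first-stage
state with two actions. Action 0 leads to second-stage state B with
probability 0.7 ("common" transition) and to state C with probability
0.3 ("rare"); action 1 mirrors this. Each second-stage state offers two
actions, and the chosen one pays a unit reward (worth EUR 0.10) with a
probability that drifts across trials.

The four reward probabilities follow independent Gaussian random walks:
at each trial, zero-mean noise with SD 0.025 is added and the proposal
is mirror-reflected back into the allowed range, re-applying the
reflection until it lands inside. Two conditions differ only in that
range: *narrow* (0.25–0.75) and *wide* (0.00–1.00). Sessions have 201
trials per condition. Mirror reflection (rather than clipping) was
chosen because it preserves the step-size distribution near the
boundaries; walk starting points are drawn uniformly within the bounds
(a fixed-value mode exists for tests), and the four walks are mutually
independent. Response deadlines are not simulated — synthetic agents
always respond — but the trial data model represents aborted
(response-less) trials so that logs of real sessions parse and are
handled correctly downstream.

## The hybrid agent

The agent carries model-free values `Q1_MF` (two first-stage actions)
and `Q2_MF` (2 states × 2 actions), updated by SARSA(λ) temporal
difference learning after each completed trial, all right-hand values
taken *before* any within-trial update:

    Q2_MF[s2, a2] += α2 · (r − Q2_MF[s2, a2])
    Q1_MF[a1]     += α1 · (Q2_MF[s2, a2] − Q1_MF[a1]) + α1·λ·(r − Q2_MF[s2, a2])

The λ term passes the second-stage reward prediction error back to the
first stage within the trial only; eligibility traces do not carry over
across trials (the drifting reward probabilities make old traces
uninformative). Both stage-1 correction terms are scaled by α1,
including the eligibility term. Unchosen entries are never touched.

Model-based first-stage values apply the Bellman equation with the true
transition probabilities (agents, like instructed participants, know
the 70/30 structure; there is no transition learning):

    Q1_MB[a] = 0.7 · max_a' Q2_MF[dest(a), a'] + 0.3 · max_a' Q2_MF[other, a']

The net value is the mixture `Q1_net = ω·Q1_MB + (1−ω)·Q1_MF`, with
ω ∈ [0, 1] constant across trials. First-stage choice is softmax in
`β1·(Q1_net(a) + π·rep(a))` where `rep(a)` is 1 for the previous
trial's first-stage action (0 for both actions on the first trial; the
memory is retained across aborted trials, perseveration being a
choice-history effect). Second-stage choice is softmax in `β2·Q2_MF` of
the visited state — the net second-stage value equals the model-free
value.

The seven free parameters: learning rates α1, α2 ∈ [0,1], inverse
temperatures β1, β2 ≥ 0, trace weight λ ∈ [0,1], perseveration bonus π
(sign-unbounded; negative = switching), and the model-based weight ω.
Q values are initialized at 0.5, the midpoint of the unit reward and
the neighborhood of the walks' mean; this is configurable, and
initialization-independent properties are tested at 0 as well.
Rewards are coded {0, 1} inside the model; the 10-cent magnitude enters
only payoff accounting, consistent with the magnitude of typical β
estimates (up to ~13.5) under unit coding.

## Likelihood and fitting

A session's likelihood replays it deterministically: for each completed
trial, accumulate −ln P(first choice) − ln P(second choice) under the
current values, then apply the observed outcome's updates. Aborted
trials contribute neither likelihood terms nor updates. With β1=β2=0
every choice probability is ½, giving the exact reference value
NLL = 2T·ln 2 for T completed trials.

Estimation is per subject and per condition: a full-factorial grid
search over a coarse grid (learning rates, λ, ω on {0.1, 0.3, 0.5, 0.7,
0.9}; β's on {1, 3, 5, 8, 12}; π on {−0.5, 0, 0.25, 0.5}; 62,500
points, capped at 200,000) followed by bounded L-BFGS-B refinement from
the 12 best grid points. Grid evaluation is vectorized over parameter
sets (the replay recursion carried as arrays over candidates), which
makes the full grid cheap; a separate scalar path serves the local
optimizer, and the two are cross-checked against each other in tests.
Refinement bounds are [0,1] for α's, λ, ω; [0,20] for β's; [−5,5] for
π — chosen to comfortably contain all reported percentile estimates.
Convergence tolerance is 1e−6 on the NLL with a 500-iteration cap per
start; results are deterministic given the session and starts. By
default each condition's starts come from its own grid (no cross-talk
between conditions); a pooling flag merges the two conditions'
candidate lists for users who prefer pooled starts. Both two-option
softmaxes are evaluated as logistics of the value difference via
`log1p(exp(·))`/`logaddexp`, which is exact and overflow-safe within
the parameter bounds.

## Behavioral read-outs

Stay behavior: for each pair of consecutive completed trials, classify
by the previous trial's transition type and reward and score whether
the first-stage choice repeats. Pairs straddling an aborted trial are
dropped entirely (conservative), the first trial is never a stay
target, and zero-count cells propagate as missing rather than 0, which
would bias the difference scores. From the four cell probabilities:

    mf_diff = (common_rewarded + rare_rewarded) − (common_unrewarded + rare_unrewarded)
    mb_diff = (common_rewarded + rare_unrewarded) − (rare_rewarded + common_unrewarded)

A purely model-free agent (ω=0) shows mf_diff > 0 with mb_diff ≈ 0 (a
main effect of previous reward); a purely model-based agent (ω=1)
shows mb_diff > 0 (the transition-by-reward interaction). Sessions are
analyzed separately per condition, and payoffs are EUR 0.10 per
rewarded trial.

## Synthetic cohorts

Because no trial-level data ship with this package, a cohort generator
emulates the study design: each synthetic subject gets one parameter
vector and runs 201 narrow plus 201 wide trials with independently
seeded walks (a yoked-walk mode shares trajectories across subjects for
variance reduction). Group presets anchor parameters at median
estimates reported for younger and older adults split by
working-memory span (e.g. younger/low-span/narrow: β1=3.91, β2=4.71,
α1=0.63, α2=0.49, λ=0.23, π=0.21, ω=0.57; older/low-span/narrow:
ω=0.24). Draws are independent truncated normals — only medians and
quartiles are reported for the original cohorts, so no covariance
structure is recoverable — with sd = IQR/1.349 (the normal-theory
conversion), scalable per group; sd_scale=0 fixes every subject at the
medians. A subject's parameters are constant across both conditions,
so per-condition reported medians serve as alternative anchors rather
than within-subject targets.

## Parameter recovery

The validation surface is recovery: simulate agents at known
parameters, refit every session with the full grid-plus-refinement
pipeline, and compare. Each condition is fitted independently; a
subject's recovered value is the mean of the two per-condition
estimates. The headline experiment uses 50 subjects with ω ~ U(0,1)
and the remaining parameters fixed at the younger/low-span medians
(402 trials each); recovery quality is summarized by the Pearson
correlation, bias, RMSE and median absolute error per parameter.
A second configuration draws all seven parameters from the preset
truncated normals (20 subjects) to check that α2 and β2 also track
their true values when the population varies; it is smaller because
per-subject fits dominate runtime and the correlation check does not
need the larger sample.

## What the synthetic data do and do not show

The generator reproduces the study's structural conditions (transition
probabilities, walk dynamics, trial counts, parameter ranges) but not
features of real behavior outside the hybrid model: response-time
structure, lapses and response deadlines, session-order or practice
effects, parameter covariance within subjects, or transition-structure
learning. Passing recovery therefore certifies the estimation pipeline
under the model's own assumptions — it does not certify the model as a
complete account of human choice.

## Known limitations

- The grid is coarse by design; refinement can stop at local optima for
  weakly identified subjects (low β1 makes ω nearly unidentifiable).
- λ and π are weakly identified in 201-trial sessions; their recovery
  correlations are expected to be modest.
- The likelihood treats aborted trials as purely missing; if abortions
  were value-dependent in real data this would be misspecified.
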