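# Methods

## Task model

The simulator reproduces a three-phase instrumental learning task with
magnitude rewards on a 0–100 point scale.

**Rewards.** Each stimulus pays from a normal N(μ, σ) truncated to
[μ − 3σ, μ + 3σ] intersected with the 0–100 display range — the stated
interval [μ − 3σ, μ + 3σ] ∩ [0, 100] is contradictory for A1/A2
(μ + 3σ = 103), and the intersection is the only reading consistent with a
0–100 display. Sampling is by rejection: exact, and cheap since at most a
fraction ~0.003 of mass is rejected (plus the small clip above 100 for
A1/A2, whose truncated mean is 63.96 rather than 64 — checked against
`scipy.stats.truncnorm` in the tests).

**Schedules.** The two contexts are interleaved pseudorandomly in shuffled
blocks of two (one trial per context per block), guaranteeing equal exposure
at every even trial count; the exact constraint used in the original
experiment is unspecified, so the block design is this package's choice.
Within each context every stimulus appears on the left in exactly half of
its scheduled trials. The transfer schedule is a shuffled 4-regular multiset
over the 6 unordered pairs with counterbalanced sides; estimation presents
each stimulus 4 times.

**Stopping rule.** From trial 100 the learning phase ends as soon as the
means of the rewards the agent has *observed* for A1 and A2 differ by less
than 1 point (factual outcomes only under partial feedback; factual and
counterfactual under complete, since both are displayed); runs still
unmatched at trial 300 are flagged excluded. If one of A1/A2 has never been
sampled the criterion is unevaluable: `stopping_decision` signals a
degenerate history, and the simulator runs such agents to trial 300 and
excludes them. This situation is not an edge case of the code but a real
behavior of opposing learning (see "lock-in" below).

**RNG contract.** One root seed per agent; three child streams (schedules,
play, estimation noise) spawned in a documented order, so seeded runs are
bit-reproducible. Cohorts derive per-subject seeds from the root
`SeedSequence` with distinct spawn keys.

## Model families

All families share one state vocabulary (per-stimulus values Q, per-context
reference values V, per-stimulus experience weights N, reward histories) and
the softmax choice rule p(ch) = 1/(1 + exp(β(Q_un − Q_ch))). Only the two
stimuli of the current context are ever touched by an update. Decisions made
where the sources were silent or ambiguous:

* **Initialization.** All Q and V start at 0 (configurable; 50 = scale
  midpoint available for sensitivity checks). Zero initialization makes the
  OL1 antisymmetry exact — within a pair Q_un = −Q_ch at all times — which
  matches the relative-encoding interpretation of the model.
* **Reference-point ordering.** V_x is updated first and the chosen/unchosen
  prediction errors use the *updated* V_x, following the order in which the
  equations are written; a regression test pins this choice.
* **RelAsym contextual reward.** The variant feeding the reference point is
  not specified; the default is the direct form (r_x = r_ch), with
  average/max variants available. The flipped sign condition for the
  unchosen option (confirmatory rate when δ_un < 0) is implemented as
  printed: a drop in the forgone option's value confirms the choice made.
* **EWA.** Experience weights are per-stimulus, N(0) = 1: each presented
  option's own N decays and increments when its value is updated (the
  printed equations use a single N(t) symbol; the per-option reading matches
  the state declaration used throughout). The counterfactual weight is fixed
  to 0 under partial feedback. The two printed value-decay symbols (φ/ϕ) are
  treated as one parameter.
* **SBE.** The printed recency weights α(1−α)^(t−i) do not sum to 1, so they
  are renormalized per trial over each option's available samples (an
  unnormalized variant is exposed behind a flag); an option with no samples
  contributes a single pseudo-sample at the initial value with probability
  1. The likelihood is the exact double sum over sample pairs, O(T²) per
  subject — acceptable at ≤ 300 trials.
* **Extended-OL reduction.** Algebra on r_hyb = r_FC − (1−w)·r_CF gives the
  transformed means μ₁′ = μ₁ − (1−w)μ₂ and μ₂′ = μ₂ − (1−w)μ₁ (reward SD
  scaled by √(1+(1−w)²)), i.e. the hybrid prediction error *widens* the
  effective mean separation to (2−w)(μ₁−μ₂). The numerical equivalence test
  confirms this transform reproduces extended-OL choice frequencies; the
  additive variant (μ₁′ = μ₁ + (1−w)μ₂) does not.

**Lock-in.** With zero initialization and all-positive rewards, moderate-β
agents of most families self-reinforce their first-exploited option: for
OL1, exploiting B drives Q_B → μ_B and Q_A1 → −μ_B, a ~2μ_B value gap.
Greedy agents therefore do *not* approach perfect accuracy (the classic
argument for optimistic initialization); tests of the greedy limit use
optimistic starts. Lock-in also produces near-deterministic choice sequences
whose likelihood is flat in all parameters above a β threshold — the main
driver of parameter-recovery noise (below).

## Fitting

Per-subject MAP: minimize learning-phase NLL − Σ log Beta(1.2, 1.2) over
each fit-space coordinate in [0, 1], by L-BFGS-B from prior-sampled starts
(default 10 restarts, objective tolerance 1e−8). β is fitted on [0, 1]:
values live on a 0–100 scale so plausible β is well below 1 (fitted means
are ≤ 0.37); the bound is configurable. OL2's constraint 0 < α₂ ≤ α₁ is
enforced by parametrizing the ratio α₂/α₁ ∈ (0, 1] as the free coordinate.
Missed trials contribute neither a likelihood term nor a state update (no
outcome was delivered). BIC = 2·NLL + k·ln(n) with n the subject's answered
trials (phase lengths are adaptive), AIC = 2·NLL + 2k. Transfer prediction
replays learning at the MAP point, freezes the end-of-learning values, and
scores the 24 transfer choices with the learning-phase MAP β (no refit),
reporting the total and the (A1, A2)-pair subtotal.

An ML mode (`use_prior=False`) exists because the nested-model inequality
(e.g. OL2 ⊇ SQL at ratio → 0) is a likelihood property: the Beta(1.2, 1.2)
log-density diverges at the boundary and legitimately keeps the MAP away
from the embedding edge.

The hot path replays a learning phase in a single numba-compiled loop;
the pure-Python step rules are the reference implementation and the tests
require exact agreement between the two, as well as agreement with an
independently transcribed oracle.

## Model selection

Random-effects Bayesian model selection with −BIC/2 as the log-evidence
proxy: a Dirichlet posterior over model frequencies (uniform prior
concentration 1) and categorical per-subject assignments, iterated to
convergence. Exceedance probabilities by Monte-Carlo over the Dirichlet
(10⁶ draws, seeded) with the analytic Beta tail used (and cross-checked)
at M = 2. The Bayes omnibus risk compares the variational free energy of
the random-effects model against the null of uniform frequencies,
BOR = 1/(1 + exp(F1 − F0)), and pxp = (1−BOR)·xp + BOR/M. AIC selects
per-subject winners in the recovery studies; BIC feeds the BMS — the two
roles are deliberately kept as in the study design.

## Synthetic cohorts and the simulation experiments

Cohort parameters are sampled from independent beta distributions
moment-matched to the fitted-parameter summaries (mean ± SD per model and
regime); the forgetting model is absent from those summaries, so its
generating values (β 0.07±0.03, α₁ 0.25±0.2, decay α₂ 0.8±0.15) are this
package's realistic choices. Infeasible moment matches (SD² ≥ m(1−m)) raise
with the offending parameter named.

The correlation experiment runs the opposing learner on one isolated pair
with plain SD-1 normal rewards (the normalised simulation scale), computes
the within-run Pearson correlation of the two value series after burn-in,
and averages over runs (SE over runs; the across-runs estimator variant is
a parameter choice away). The *default burn-in is adaptive*: the sum mode
Q₁+Q₂ relaxes at ≈ (α₁−α₂)/2 per trial (it is exactly conserved at
α₂ = α₁), and a fixed 50-trial burn-in demonstrably leaves transient
contamination at intermediate ratios (measured −0.15 instead of −0.75 at
ratio 0.75 with 1,000 trials); the default discards max(50, six time
constants), capped at half the series. An explicit `burn_in` argument keeps
the fixed variant. The performance grid uses common random numbers across
the α₂/α₁ axis so ratio comparisons are paired.

Estimation-phase responses are modeled as the frozen value plus zero-mean
Gaussian noise (SD 5 points), clipped to 0–100 — an artifact convention;
nothing in the sources models estimation responses. Transfer choices use
the same β as learning.

## What the synthetic data do and do not show

The generator emulates the trial structure, reward statistics, adaptive
stopping, and softmax-agent choice of the study conditions. It does not
emulate reaction times, confidence ratings, attention lapses beyond simple
missed trials, or any within-session nonstationarity of real participants.
Passing tests therefore demonstrate internal correctness of the pipeline
and the simulation-level claims (correlation law, performance ordering,
recoverability at the stated cohort sizes), not behavioral conclusions
about human data.

## Problem sizes and known limitations

* Acceptance-scale studies run at reduced size as the package's own choice:
  correlation 20 runs × 1,000 trials; performance 200 reps × 200 trials;
  parameter recovery one 30-subject cohort with 10 restarts; model recovery
  5 generating models × 5 cohorts × 10 subjects with 3 restarts per fit.
* Parameter recovery at 30 subjects is noisy by construction: the
  moment-matched β distribution (mean 0.02, SD 0.02 ⇒ Beta(0.96, 47)) has
  mode 0, so a few subjects per cohort carry almost no choice information
  (β ≈ 0, near-random choice) or are locked-in (flat likelihood), and their
  MAP lands at the prior mode 0.5. Pearson r(α₁) then fluctuates around
  ~0.45 across seeds — often below 0.5 at this cohort size, while pooled
  regression slopes stay positive. Larger pooled studies (see
  `analysis/05_parameter_recovery.py`) stabilise the estimates.
* The model-recovery confusion matrices show the expected mimicry: models
  sharing degeneracies (hybrid at w = 1 vs standard Q-learning; forgetting
  with strong decay vs opposing learning) mix, while OL1's posterior
  diagonal dominates its column.
* BMS assumes independent subjects and trusts −BIC/2 as evidence; no
  hierarchical parameter estimation is attempted (subjects are fitted
  independently by design).
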