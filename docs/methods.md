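# Methods

This note documents the models, estimators and numerical choices behind
`pvtvuln`, and what the synthetic cohort does and does not establish.

## The prediction problem

A 10-min PVT presents a visual counter at random 1–9 s inter-stimulus
intervals; the participant responds as fast as possible. A *lapse* is a
reaction time above 500 ms. Vulnerability to total sleep deprivation (TSD)
is defined behaviourally: rank participants by their mean lapse count over
the five sessions taken 16–24 h after waking, and call the lowest quartile
resilient, the highest vulnerable, the middle half intermediate (1:2:1).
The package asks whether features of a *single rested baseline session*
(4–14 h awake) can predict that label.

## Synthetic cohort model

No public trial-level dataset exists for this protocol, so the generator is
a first-class, tested component. Per trial, the RT is a two-state mixture:

* attentive: RT ~ LogNormal(base_speed + drift·minute, base_sd), with
  drift = 0.004 log-ms/min modelling mild within-session slowing;
* lapse: RT = 500 · U^(−1/α) ms (shifted Pareto, α = 1.6, mean ≈ 1.33 s),
  capped at 30 s; a draw beyond the cap is recorded as a response timeout.
  The heavy tail is what threshold-based lapse metrics need; the protocol
  itself prescribes no RT distribution.

The per-trial lapse probability is logistic:

    logit p = lapse_propensity
            + homeo_gain · max(0, t_awake − 16)
            + circ_amp · cos(2π (t_awake − circ_phase) / 24)
            + tot_gain · minute_in_session

Homeostatic pressure grows only past 16 h awake; the circadian term peaks
at the participant's alertness minimum (circ_phase ≈ 22 h after wake,
i.e. the usual early-morning nadir, used as a phase proxy because the
protocol measures no circadian phase); time-on-task adds 0.05 logits/min.
False starts (RT < 100 ms, 2 % of trials) and wrong-button presses (1 %)
are injected so QC and error-count features are exercised.

Traits are constant within participant. A latent vulnerability factor v
and a baseline factor u = ρ·v + √(1−ρ²)·ε couple the baseline traits
(base_speed, base_sd, lapse_propensity ← u) to the homeostatic gain (← v),
so corr(base_speed, homeo_gain) = ρ exactly (ρ = `trait_correlation`).

**Calibration (done once, then frozen).** The population parameters
(lapse_propensity −3.72 ± 0.50, homeo_gain 0.33 ± 0.075 h⁻¹, circ_amp
0.55 ± 0.20, ρ = 0.45) were chosen by a coarse grid search against the
study-level statistics the protocol reports: vulnerable/intermediate/
resilient quartile ranges of mean TSD lapses (≈ 0–14 / 14–30 / 31–53),
baseline lapses explaining ≈ 50 % of TSD variance (measured R² ≈ 0.56),
and ≈ 37 % of participants at ≤ 2 baseline lapses per session. These
targets are part of the stated world; they were not adjusted afterwards.

**What the generator does not emulate:** learning effects, motivation and
effort fluctuations, sleep-history carry-over, inter-day trait drift,
device timing artefacts, and any correlation structure beyond the single
latent factor. A green end-to-end test therefore establishes that the
pipeline recovers planted trait structure of realistic magnitude — not
that it would achieve the same accuracy on human data.

All randomness derives from one master seed through keyed `SeedSequence`
streams — (seed, participant-hash, day, time) per session — so any session
is reproducible in isolation and whole studies are bit-identical.

## Quality control

Operationalisations the source rules leave open:

* "no RT recorded for > 1 min" = any gap > 60 s between consecutive
  recorded responses, **including** session start → first response and last
  response → session end;
* wrong-button fraction uses all recorded trials (timeouts included) as
  denominator;
* an invalid *baseline* session never excludes a participant; that
  participant is simply absent (complete-case) from the affected
  per-time-point model.

## Features

216 measures per session (default grids): 4 central-tendency, 19
percentiles (5–95 step 5), 171 ordered percentile differences, 5 lapse
counts (thresholds 355/500/1000/2000/5000 ms — 355 ms standing in for
eyes-closed-probability thresholds), 3 error counts, 3 variability, 5
consecutive-difference, 4 time-on-task, 2 tail means. Conventions: false
starts (< 100 ms, the standard PVT convention) and timeouts are excluded
from RT-distribution statistics; timeouts count as lapses at every
threshold; reciprocal RT is 1000/RT (s⁻¹); quantiles use linear
interpolation (numpy default, type 7); time-on-task slopes are OLS per
minute and undefined (NaN) when fewer than 2 responses or < 1 min span;
SDs use ddof = 1. The original instrument's exact 426-measure list is not
public; the catalog reconstructs every named family with grids of
comparable scale, and the serialised catalog (JSON) is the ground truth
for ordering and count.

## ICC screening

For each feature at each baseline time point, values from days 2, 3, 4 at
the same time-since-wake enter value = day-effect + participant-intercept
+ noise; ICC = σ²_BS/(σ²_BS + σ²_WS) with components estimated by REML and
negative estimates truncated at 0. Complete balanced tables use the exact
closed form (two-way mean decomposition — identical to iterative REML, and
tested against statsmodels MixedLM to 1e-6); unbalanced tables fall back
to MixedLM (Powell optimisation, which converges much tighter here than
L-BFGS). σ²_WS is the pure residual after the day effect (no
day×participant interaction term). Features with ICC strictly > 0.60 pass;
a feature observed on < 50 % of participants is skipped with a warning.
Screening is per time point, so the six models may use different candidate
sets. All-identical values yield ICC = 0 by convention.

## Classifier

Pooled-covariance LDA on z-scored features (training-fold moments,
ddof = 0; a constant training column gets σ = 1 and z = 0). With class
means m_k and pooled within-class covariance S (denominator n − 3,
optionally shrunk toward its diagonal), g_k(z) = w_k·z + c_k where
w_k = S⁻¹m_k and c_k = −½ m_k·S⁻¹m_k + log π_k; priors are empirical class
frequencies, and softmax(g) is the exact Gaussian-Bayes posterior because
the quadratic term is class-independent. If S is singular (condition
number > 1e10) the shrinkage ladder {0, 0.1, 0.5, 1} is climbed with a
warning; count-valued features with many zeros make this common in small
training folds. An empty feature set degenerates to a prior-only
(majority-class) model.

Costs: the published sweep "1 to 5 in 0.5 steps" is parameterised as one
scalar c that prices misclassifying an extreme class (resilient or
vulnerable) at c and misclassifying an intermediate at 1 (zero diagonal);
any full 3×3 matrix is also accepted since the original matrix family is
unpublished. Costs act at decision time — predict argmin_j Σ_i C[i,j]·p_i —
not by reweighting the fit; at c = 1 this is exactly argmax posterior.
Ties break to the fixed class order (resilient < intermediate <
vulnerable).

## Wrapper search

Forward-selection best-first search from the empty set: expand the
highest-scoring unexpanded subset by every single-feature addition,
scoring each child at every cost in the grid (a child's score is its best
over costs, ties to the lower cost); terminate after 5 consecutive
expansions without strict improvement of the global best ("iteration" is
read as one node expansion), when candidates are exhausted, or when an
optional beam width prunes the frontier. Scoring is mean three-class
accuracy over repeated stratified 5-fold CV (default 100 repeats; fast
mode 10): within each class, participants are shuffled and dealt
round-robin, giving exactly 8/16/8 per fold at n = 160 and 3/6/3 at
n = 60. Fold draws for repeat r depend only on (master seed, r), so every
subset is scored on identical folds — a paired comparison that reduces
selection noise — and the search is a pure function of (data, config,
seed). Z-scoring and fitting use training folds only. The winning (subset,
cost) is refit on all participants.

## Evaluation

Metrics are computed within each CV run and summarised mean ± SD across
runs. Cohen's kappa uses marginal-product expected agreement; chance
accuracy for class counts n_k is Σ(n_k/n)² (0.375 at 1:2:1 — the printed
37.4 % differs by rounding/simulation in the source). Zero-denominator
rates are reported as NaN with a warning, never as 0. The modal
(most-frequent) prediction across runs gives each participant's group
assignment; modal ties break to the fixed class order. Group time courses
are mean ± SEM lapse counts per assigned group at every session slot.

## Known limitations

* With no informative features, empirical-prior LDA predicts the majority
  class and scores ≈ 0.5, above the 0.375 permutation chance level; the
  correct no-information null is label-independence (kappa ≈ 0), which the
  tests assert.
* Wrapper CV accuracy is optimistically biased (features are selected on
  the same CV machinery that scores them); no outer validation loop is
  implemented, matching the original design.
* MixedLM fallback is ~100× slower than the balanced closed form; heavily
  unbalanced studies make screening the dominant cost.
* The cost-matrix family and the ≤ 2-lapse subgroup rule ("mean over the
  six baseline sessions", chosen over "every session") are documented
  interpretations of under-specified source rules.
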