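# Methods

This note documents the models and procedural rules `switchbf` implements,
the defaults and why they were chosen, and what the synthetic-data tests do
and do not establish about real data.

## The experimental design being emulated

A cued task-switching session consists of 7 blocks × 64 trials. Each
stimulus conjoins four binary features — colour (red/green), shape
(circle/triangle), vertical position (up/down) and horizontal position
(left/right) — and on every trial a cue designates one dimension as the
task. All four tasks share two response keys, so each irrelevant dimension
activates an S-R rule that either agrees with the correct response
(compatible) or points at the other key (a *competitor*). Task order is
random under a 100%-switch constraint (the successor task is drawn
uniformly from the other three), stimuli are drawn uniformly from the 16
feature combinations, and the 8 response mappings (horizontal key
arrangement × colour assignment × shape assignment; `up` is always on the
upper key) are counterbalanced within each experimental group.

## Generative model

Reaction times are ex-Gaussian around a linear predictor:

    rt = base − spatial_advantage·1[spatial task] + slope·n_competitors
         + bi_cost·1[ABA] + crs_cost·1[CRS+] + intercept_participant
         + Normal(0, σ) + Exponential(τ)

with errors Bernoulli(base_error_rate + error_slope·n_competitors). Trials
are classified (competitor count, BI and CRS labels) *before* RTs and
errors are drawn, so the generator's effect parameters act on exactly the
features the analysis conditions on, which is what makes parameter-recovery
testing meaningful.

Defaults are set to the magnitudes the emulated study reported for its
indices: slope 34 ms/competitor (linear-congruency index ≈ 340 ms since the
contrast weights (−3,−1,1,3) against levels 0..3 sum to 10× the slope),
bi_cost 26 ms, crs_cost 28 ms, error slope 0.017/competitor (PE index
≈ .17), zero BI/CRS effects in errors. Where no magnitude is stated the
defaults are conventional for RT work: σ = 50 ms, τ = 100 ms, participant
intercept SD 100 ms, spatial-task advantage 50 ms, base error rate 0.08.
The RT distribution's exact shape is a stand-in — ex-Gaussian is the
standard choice — and nothing downstream depends on it beyond having a
realistic skew.

Group differences on the cognitive indices default to zero (the emulated
study's outcome). When a nonzero Cohen's d is requested for an RT index,
the anti group's effect parameter is shifted by d × (per-index SD), using
scale constants calibrated once by Monte Carlo under the default noise
parameters (85 ms for the congruency index, 14.5 ms for BI, 42 ms for CRS;
the congruency shift is divided by 10 to act on the slope). These constants
are part of the generator's definition, not estimates refreshed at run
time; with different noise parameters the realized d will deviate
accordingly.

Questionnaires: a participant's latent free-will-belief score is Normal
(pro group mean 4.65, the anti group shifted down by fwi_group_d × 1.20,
default d = 0.70); the five items add Normal(0, 0.9) noise and are rounded
and clipped to 1..7. Recovery simulations put the realized composite d at
0.70 and Cronbach's alpha near .88 (reported: .87). Fatigue uses the same
construction (alpha ≈ .80 vs reported .79) with `alert` and `energetic`
generated — and scored — reverse-coded as 8 − rating, so a high composite
means more fatigue. Locus of control draws 23 Bernoulli items from a
participant-level internality propensity (logit-normal), matching the
reported composite mean and SD (~9.6 ± 4); with exchangeable Bernoulli
items its alpha (~.65) falls short of the reported .80, a known limitation
of this simple item model that nothing in the pipeline depends on.

## Trial classification

* **Competitor count**: irrelevant dimensions whose activated rule maps to
  a key other than the trial's correct response (0..3; over the 16 stimuli
  the exact distribution is {0: 2, 1: 6, 2: 6, 3: 2} for any task and
  mapping).
* **Backward inhibition**: within a block, trial N with two predecessors is
  ABA if task(N) = task(N−2), else CBA. With four tasks 1/3 of
  classifiable trials are ABA, so a session yields ≈140 ABA and ≈280 CBA
  trials after first-four removal.
* **CRS**: defined only on response alternations (correct keys of N−1 and
  N differ). CRS+ when the feature of N's relevant dimension repeats from
  N−1 — with two shared keys and an alternation that rule necessarily
  competed on N−1; CRS− when that feature changed (the previously activated
  rule of that dimension was compatible).
* **Controls on CRS cells**: *competitor-rule priming* invalidates trial N
  when any dimension irrelevant in both trials repeats a rule that competed
  on N−1 (carry-over suppression of a rule that is merely primed, not made
  relevant, would contaminate both cells); *competitor-remains-competitor*
  additionally requires that rule to compete again on N (with two keys this
  can only occur outside response alternations, where CRS is undefined
  anyway — the flag is kept for completeness and for generalised designs).
* **Interference equating**: CRS+ implies at least one competitor on trial
  N−1 and CRS− at most two, so both cells are restricted to the common
  support (1..2 competitors on N−1); the current trial's interference is
  equated by computing cell means within competitor-count strata and
  averaging strata populated in both conditions with equal weights. Under
  these rules a simulated session retains ≈46 CRS+ and ≈33 CRS− analysable
  trials (≈39 per condition on average); the asymmetry is a consequence of
  the equating rules, not of the sequences.

Trial-level exclusions: the first four trials of each block, the two
within-block trials following an error, and full stimulus repetitions (all
four features repeat — the feature-binding confound) are excluded from all
analyses; error trials and RTs outside 100–3000 ms are excluded from RT
analyses only. Excluded trials still serve as sequence context for their
successors. All sequential definitions stop at block boundaries.

## Index computation

Because tasks are sampled randomly, conditions can over-represent tasks,
and spatial tasks are generated faster than object tasks; cell means are
therefore computed per task first and averaged across tasks with equal
weights. RT cells use correct, in-bounds, non-excluded trials; PE cells use
all non-excluded trials. Missing cells propagate to a missing (NaN) index,
never to zero.

One subtlety worth knowing: with *all* effects active, the three indices
are not perfectly orthogonal — the Hommel exclusion makes CRS+ membership
slightly competitor-count-dependent, so the CRS cost leaks about −6 ms
(≈2%) into the congruency contrast at default parameters. Recovery tests
therefore simulate each effect in isolation, where recovery is exact in
expectation; BI and CRS are unaffected because their cells have identical
competitor-count composition (by independence and by explicit equating,
respectively).

## Participant exclusion

Applied in the study's order: (1) incomplete data and the optional practice
gate; (2) the 40% error cap, computed on all trials *before* any robust
statistics; (3) the 2.5-MAD rule on overall RT and overall PE within each
group, with the 1.4826 normal-consistency constant (a zero MAD retains only
exact-median values and warns); (4) minimum trials — at least 20 per
condition and 5 per task per condition for every condition of every
computed index, counted on the RT-analysis trial set; (5) an optional
offset-delay filter on recorded timing metadata with configurable
comparator (default: exclude when the mean exceeds 30 ms or the SD exceeds
36 ms), the direction being surfaced in the exclusion report because the
source description of this rule is ambiguous. The cascade is deliberately
strict: at default generator parameters roughly half to two-thirds of
simulated participants fail the per-task CRS cell minimum, which mirrors
the high exclusion rates this preprocessing regime produces in practice.

## Bayes factors

The two-sided JZS factor is evaluated through the normal-scale-mixture
representation of the Cauchy prior (inverse-gamma(1/2, 1/2) on the mixing
variance): a one-dimensional integral of elementary functions, computed in
log space with 300-node Gauss–Legendre quadrature after mapping the
half-line to (0, 1). It matches an adaptive-quadrature oracle over the
effect-size prior, and pingouin's implementation, to better than 1e−8
relative. Directional factors truncate the prior to one sign; substituting
δ = r·tan(πu/2) absorbs the half-Cauchy density exactly, leaving the mean
of noncentral-t likelihoods over the quadrature grid. Correlation Bayes
factors use the exact sampling density of Pearson's r (hypergeometric form)
under a stretched-beta prior of width 1 (uniform on (−1, 1)), configurable.
Evidence categories follow the conventional thresholds 3/10/30/100 with
boundary values assigned to the weaker category and BF = 1 labelled
anecdotal without direction. Effect sizes: d = t·√(1/n₁+1/n₂),
η²ₚ = t²/(t²+df). Power is exact via the noncentral-t distribution.

## Sequential design simulator

Each simulated study draws its groups from Normal(d, 1) and Normal(0, 1) —
the standard design-analysis data model; the trial-level generator is
exercised by the pipeline modules, not here. Looks start at n_min = 60 per
group and add one participant per group (configurable batch accrual) up to
n_max = 100; boundaries default to 10 and 1/10, with BF > 3 / < 1/3 judged
at n_max. Draws are made once per study and looks reuse cumulative
sufficient statistics; within a look the directional log-BF is interpolated
from an 80-node cubic spline in t (the function is smooth and monotone;
interpolation error < 1e−5 in log BF, far below boundary-classification
relevance), which keeps 10,000-study analyses at a few seconds.

The simulator's default is the *directional* (one-sided) Bayes factor.
The choice was resolved empirically: only the one-sided variant reproduces
the published operating characteristics (at d = 0.5: 83% upper-boundary
hits, 89% total evidence for H1, mean stop ≈ 72; at d = 0: 58%
lower-boundary hits, 86% total evidence for H0). The two-sided variant
cannot even reach the lower boundary at these sample sizes (its BF at t = 0,
n = 100/group is ≈ 0.11 > 1/10), which also explains why a directional
factor is the sensible choice for a design meant to stop on H0 evidence. Note that the mean stopping
point is *not* monotone in d: studies stop early both under strong effects
(upper boundary) and under the null (lower boundary), and run longest near
d ≈ 0.25 where neither hypothesis accumulates evidence.

## Problem sizes used in validation

The test suite simulates 500 participants per recovery scenario, 500
sequence-only sessions for trial-count expectations, and 2,500 sequential
studies per design-analysis condition; `scripts/acceptance.py` uses 10,000
studies per condition and 500 sessions. These sizes put Monte-Carlo
standard errors comfortably below the tolerances being asserted (e.g.
binomial SE ≈ 0.4 percentage points at 10,000 studies).

## What passing tests do and do not show

The synthetic generator emulates the *design* of the study — its trial
structure, counterbalancing, effect magnitudes and questionnaire score
distributions — not the full texture of real data: no practice or fatigue
drift within a session, no sequential RT autocorrelation beyond the
modelled effects, no item-level questionnaire structure, no device-timing
artefacts (offset-delay metadata is generated as plain Gaussian noise).
Passing recovery tests shows the pipeline is an unbiased estimator of the
effects *as defined by this generative model*; it cannot certify the
psychological interpretation of the indices, nor the behaviour of the
exclusion cascade under real-world missingness patterns.
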