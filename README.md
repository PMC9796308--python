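# switchbf

Task-switching cognitive-control indices and Sequential Bayes Factor (SBF)
design analysis.

`switchbf` is built for experimental psychologists who study cognitive
control with cued task-switching paradigms and plan or analyse their studies
with default-prior Bayes factors. It bundles four things that usually live
in separate scripts:

1. **A generative simulator** of a four-task cued switching experiment:
   two groups of participants, 7 blocks × 64 trials each, 100%-switch task
   sequences over four binary classification tasks (colour, shape, vertical
   and horizontal position), 16 stimuli, 8 counterbalanced response
   mappings, ex-Gaussian reaction times with known effect parameters,
   competitor-dependent errors, and questionnaire batteries (a 5-item free
   will inventory subscale, 4 fatigue ratings, the 23-item locus of control
   scale).
2. **The trial classification and exclusion pipeline** for three indices:
   - *linear congruency*: each trial has 0–3 competitor stimulus–response
     (S-R) sets — irrelevant dimensions whose activated rule points at the
     wrong key; per-participant cell means over the four levels are
     combined with the linear contrast weights (−3, −1, 1, 3);
   - *backward inhibition (BI)*: the RT/error cost of ABA task triplets
     (returning to a just-abandoned task) over CBA triplets;
   - *competitor rule suppression (CRS)*: the cost when a rule that
     competed on trial N−1 becomes the relevant rule on trial N (CRS+)
     versus a matched baseline (CRS−), analysed only on response
     alternations and equated for the degree of interference.
3. **A JZS Bayes-factor engine**: one- and two-sample t-test Bayes factors
   under a Cauchy prior on the standardized effect (numerical integration,
   vectorised), default Bayesian correlation tests, Jeffreys evidence
   categories, Cohen's d / partial eta squared, and exact noncentral-t
   power.
4. **An SBF design simulator**: Monte-Carlo operating characteristics of a
   sequential sampling plan that starts at n_min per group, recomputes
   BF10 after every added participant, and stops at boundaries (default 10
   and 1/10) or at n_max.

## The statistics in brief

For a two-sample t statistic the default Bayes factor is

    BF10 = ∫ p(t | δ) Cauchy(δ; 0, r) dδ / p(t | 0),

with p(t | δ) the noncentral-t likelihood at noncentrality δ√(n₁n₂/(n₁+n₂))
and r = 1 by default. Directional hypotheses truncate the prior to one
sign. An SBF design with boundaries (1/10, 10), n from 60 to 100 per group
and a directional BF reproduces the operating characteristics this kind of
registered design reports: with a true effect of d = 0.5 roughly 83% of
studies stop at the upper boundary (~89% end with evidence for H1) at a
mean stopping point of ~73 per group, while under d = 0 about 58% stop at
the lower boundary (~86% end with evidence for H0).

## Worked example

```python
import numpy as np
from switchbf import SBFDesign, run_design_analysis, jzs_bf_two_sample, power_ttest

res = run_design_analysis(SBFDesign(true_effect_d=0.5), n_sims=10_000, rng=42)
print(res.proportions["hitUpper"], res.evidence_h1_total, res.mean_stop_n)
# 0.831 0.8939 72.1487

rng = np.random.default_rng(0)
x, y = rng.normal(0.5, 1, 80), rng.normal(0, 1, 80)
r = jzs_bf_two_sample(x, y, direction="greater")
print(round(r.bf10, 1), r.evidence, round(r.effect_d, 3))
# 3712.8 H1: decisive 0.728

print(round(power_ttest(0.5, 60), 2), round(power_ttest(0.5, 73), 2))
# 0.86 0.91
```

The first block says: under a true standardized group difference of 0.5,
83.1% of sequential studies stopped by crossing BF10 > 10, 89.4% ended with
at least substantial evidence for H1, and the average study needed ~72
participants per group. The second block tests two simulated samples and
finds decisive evidence for a group difference of d ≈ 0.73. The third line
is the exact one-sided power of a fixed-n t-test for d = 0.5 at the
design's minimum (n = 60) and average stopping (n = 73) sample sizes.

The full data pipeline is also available from the shell:

```bash
switchbf simulate --n-per-group 100 --seed 1
switchbf classify --trials trials.csv --out classified.csv
switchbf indices --classified classified.csv --out indices.csv
switchbf exclude --indices indices.csv --participants participants.csv
switchbf analyze --indices indices_filtered.csv --participants participants.csv
switchbf design-analysis --d 0.5 --sims 10000 --seed 1
```

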