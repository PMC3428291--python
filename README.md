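# drmkit

Scoring and test–retest validation tooling for the **abbreviated Day
Reconstruction Method (DRM)** — the short survey instrument that
measures experienced well-being by having respondents reconstruct part
of their previous day as episodes with activities, companions, and
seven affect ratings on a 1–3 scale.

The package is for survey methodologists and well-being researchers
who need to (a) score episode-level DRM records into the standard
summary measures, and (b) run the full psychometric battery that
validates a short form against the full-day instrument administered a
week later.

## What it computes

**Scores** (per respondent and wave): positive affect
PA = mean(calm/relaxed, enjoyment), negative affect NA = mean of the
five negative items, net affect = PA − NA ∈ [−2, 2], all
duration-weighted over episodes; and the U-index, the share of
reported time in episodes whose highest-rated feeling is negative.
Set D (coarse part-of-day blocks, no durations) gets raw means and no
U-index.

**Statistics**:

- one-way random-effects ICC with an F-pivot 95% CI
  ((MSB − MSW)/(MSB + MSW), CI from F = MSB/MSW with df (n−1, n)) and
  Landis–Koch bands;
- paired *t* with the paired-design-corrected effect size
  d = t·√(2(1 − r)/n);
- Pearson correlations with Fisher-z CIs, Spearman rank correlations;
- χ²/Cramér's V, ANOVA/Cohen's f, unpaired t/Hedges' g for set
  comparisons;
- Cohen's κ, weighted κ, and the Delta coefficient
  (chance-corrected agreement under a recognition/guessing model,
  robust to unbalanced margins) with a goodness-of-fit χ²;
- the pairwise-concordance AUC for a *continuous* gold standard
  (score 1/0.5/0 per subject pair by concordant/tied/discordant
  ordering) with a jackknife standard error;
- OLS regression of net affect on education, setting, income, sex and
  age with pairwise interactions, a nested-model F test, and one-pass
  pruning of non-significant interactions;
- per-activity duration-weighted affect profiles with a ≥5% reporting
  filter and ranking-stability correlations.

A synthetic cohort generator (`drmkit.cohort`) emulates the validation
study design — four randomized short sets at baseline, full-day
re-interview one week later, configurable latent variance components,
activity affect offsets and demographic effects — so every statistic
in the battery can be verified by parameter recovery. See
`docs/methods.md` for the model and its calibration.

## Worked example

```sh
drmkit simulate --n 1560 --seed 5 --out demo_study
drmkit validate --study demo_study --out demo_report
```

`demo_report/` then holds nine CSV tables plus `summary.json`. With
this seed, the pooled test–retest block of `test_retest.csv` reads

```
pooled net      test 1.01 retest 1.03 ICC 0.37 (0.33,0.42) fair
pooled pa       test 2.20 retest 2.21 ICC 0.36 (0.32,0.40) fair
pooled na       test 1.18 retest 1.18 ICC 0.29 (0.24,0.33) fair
pooled u_index  test 0.19 retest 0.19 ICC 0.22 (0.16,0.27) fair
```

— net and positive affect are more reproducible across a week than
the negative-emotion measures, with positive affect means near 2.2
and negative near 1.2 on the 1–3 scale. Criterion validity
(`auc_short_vs_full.csv`): the pooled A+B+C short scores predict the
full-day scores with AUC 0.63 (net), 0.62 (PA), 0.60 (NA), 0.59
(U-index), se ≈ 0.01 — of two random respondents, the one scoring
higher on the short form has ≈60–63% probability of scoring higher on
the full instrument. Within the retest, each part of the day is
strongly representative of the whole day (slice AUCs 0.83–0.86 for
net affect). The activity ranking is stable between waves (Spearman
0.90, Pearson of means 0.88), the regression retains exactly the
education×sex and income×sex interactions (final F(7, 1552) = 17.7,
adjusted R² = 0.07), and the supplementary day-feeling items show
substantial agreement with Delta ≥ kappa and adequate model fit
(e.g. *angry*: κ = 0.67, Δ = 0.77, GOF p = 0.45).

The same numbers are reachable through the library:

```python
from drmkit import CohortConfig, generate_study, run_validation

sim = generate_study(CohortConfig(n_respondents=1560, seed=5))
report = run_validation(sim.study, sim.supplementary)
report.summary["test_retest"]["pooled.net"]["icc"]   # 0.373
```

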