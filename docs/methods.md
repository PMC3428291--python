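# Methods

## The measurement problem

The Day Reconstruction Method (DRM) measures experienced well-being by
having respondents reconstruct the previous day as a sequence of
episodes, each rated on seven affect items (worried, rushed,
irritated/angry, depressed, tense/stressed, calm/relaxed, enjoyment) on
a 1–3 scale. Because the full instrument is long, an abbreviated form
randomizes each respondent to one of four short sets: A, B, C cover the
morning, afternoon, or evening episode-by-episode; D covers the whole
day in three coarse blocks without durations. Validating the short form
requires (i) test–retest reliability of its summary scores against a
full-day re-interview one week later, and (ii) criterion validity — how
well short-form scores predict full-form scores. `drmkit` implements
the scoring rules and the complete statistical battery, plus a
synthetic cohort generator so every statistic is checkable by parameter
recovery against known ground truth.

## Scoring

For one episode with ratings r, positive affect PA = mean(calm/relaxed,
enjoyment), negative affect NA = mean of the five negative items, net
affect = PA − NA ∈ [−2, 2]. An episode is *unpleasant* when its
highest-rated feeling is negative — ties between the strongest negative
and strongest positive item count as not unpleasant (strict
inequality), a convention centralized in `episode_is_unpleasant`.

Per respondent-wave, episode-based sets (A/B/C/FULL) are scored by
duration-weighted means; the U-index is the fraction of reported
minutes spent in unpleasant episodes. Set D is the unweighted mean over
its (at most three) segments and has no U-index, since no durations are
collected. Episodes missing any of the seven items are dropped with a
logged count; no imputation.

Intervals are half-open `[start, end)` integer minutes, so abutting
episodes never double-count. Parts of the day are delimited at noon
(12:00) and 18:00; morning starts at wake-up. Episodes straddling a
boundary are split with durations prorated. Whether the original
analysis split or assigned straddling episodes whole is unknowable from
the published account; splitting is the convention here because it
makes the three slices partition the reported day exactly.

## Reliability statistics

*ICC.* One-way random-effects, single-measure intraclass correlation
with k = 2 interchangeable measurements per subject:
ICC = (MSB − MSW)/(MSB + MSW). The 95% CI inverts the F = MSB/MSW pivot
with df (n − 1, n): bounds (F/F_u − 1)/(F/F_u + 1) and
(F·F_l − 1)/(F·F_l + 1). The one-way form is used because the design
treats test and retest as exchangeable within subject and no two-way
model is implied; negative estimates are reported as computed and
banded "poor". Landis–Koch bands are right-closed 0.2-wide intervals.

*Paired comparisons.* Paired t with the paired-design-corrected effect
size d = t·sqrt(2(1 − r)/n), r the between-wave Pearson correlation,
so that large-n significance is not mistaken for effect. Report layers
blank d when p ≥ α, mirroring the field's reporting habit; the value is
always computed.

*Correlations.* Pearson with Fisher-z intervals
tanh(atanh(r) ± z_{1−α/2}/√(n−3)); Spearman as Pearson on average
ranks. At |r| = 1 the z-interval collapses to the endpoint.

*Set comparisons.* χ² with Cramér's V = sqrt(χ²/(n(m−1))), one-way
ANOVA with Cohen's f = sqrt(η²/(1−η²)), unpaired t with Hedges' g
(small-sample correction 1 − 3/(4·df − 1)).

## Categorical agreement

Cohen's κ and linearly weighted κ (3-point ordinal items; quadratic
weights available; the scheme is recorded in the result) are standard.
The Delta coefficient models each recorded answer as either a genuine
recognition of the respondent's category (probability δ_i) or a random
guess from a guessing distribution; for a test–retest design the two
administrations are exchangeable, restricting expected tables to
symmetric ones. The reported estimate solves the moment equations on
the symmetrized table: δ̂_i = 1 − 2m̄/π̂_i and Δ̂ = 2p_o − 1, where m̄
is the pooled off-diagonal proportion and π̂_i the symmetrized margins.
When all δ̂_i ≥ 0 this is exactly the ML fit with the non-identified
recognition/guessing split resolved at the supremum of Δ (least
chance-attribution); below the chance floor it continues smoothly into
negative values, read like negative κ. Unlike κ, Δ does not collapse
under strongly unbalanced margins. Goodness of fit is the 1-df Pearson
χ² of the observed table against the fitted symmetric table (a
McNemar-type symmetry statistic); its p-values are calibrated under
data generated from the fitted model.

## Concordance with a continuous gold standard

When the criterion (full-DRM affect) is continuous, accuracy is the
pairwise concordance AUC: over all subject pairs with distinct gold
values, score 1 for concordant ordering by the test measure, 0.5 for a
test tie, 0 for discordant; AUC is the mean pair score. Pairs tied on
gold carry no ordering information and are excluded from the
denominator (`n_pairs_used` records the count). The standard error is
the delete-one jackknife over subjects, computed from per-subject pair
sums so it costs no more than the point estimate; a U-statistic
structural-components estimator is kept as a cross-check (the two
differ by exactly (n−1)/(n−2) when gold has no ties). The kernel is
evaluated in row blocks, keeping memory O(block·N).

## Regression

Net affect at baseline is regressed on education (0 = less than
primary, 1 = primary completed or more), setting (0 rural / 1 urban),
household income (0 = lower two quintiles, 1 = upper three), with sex
(0 female / 1 male) and age as covariates. The initial model adds all
pairwise interactions among the four binary predictors (the published
account names "interaction terms among categorical variables" without
enumerating them; the set is configurable). A nested ANOVA F test
compares it with the main-effects model, and one pruning pass drops
interactions with p ≥ α — single-pass, not stepwise, matching the
two-model narrative of the original analysis.

## The synthetic cohort generator

Latent episode affect is

    ℓ = μ0 + x'β + u_i + w_iw + a_e + ε_e,

with person trait u_i ~ N(0, σ²_between), day/wave noise
w_iw ~ N(0, σ²_within), activity offset a_e from the catalog, and
episode noise ε_e ~ N(0, σ²_episode). Item ratings threshold ℓ plus
item noise N(0, σ²_item): positive items increase in ℓ, negative items
decrease, each with two cutpoints.

Defaults and why:

- **Design**: 1560 respondents, ¼ per set, retest = FULL for all but a
  22/1560 missing-at-random dropout, one week apart — the validation
  study's design.
- **Demographics**: 53.1% female; age N(57.1, 17.6²) clipped to 18–95;
  the seven-level education distribution of the study population
  (≈42% primary completed or more); 55.6% urban; uniform income
  quintiles; 73.1% married.
- **Variance components**: σ²_between = σ²_within = 0.25 — the
  equal-variance condition the recovery battery prescribes — with
  σ²_episode = 0.30 and σ²_item = 0.50 chosen once so that episode- and
  item-level churn dominate, as they do in experience data.
- **Thresholds**: pos (−0.98, 1.14), neg (0.98, 1.25), calibrated so
  pooled marginals reproduce the field levels PA ≈ 2.2 ± 0.43,
  NA ≈ 1.16 ± 0.30, net ≈ 1.04 ± 0.66. They live in the config, not in
  code.
- **Demographic effects β** (latent scale): male +0.25, upper-income
  +0.45, urban +0.25, educated +0.30, age −0.002/yr, with
  education×sex = income×sex = −0.40 — positive main effects with
  effects stronger for women, the pattern the validation study reports.
  Thresholding attenuates these by ≈0.6–0.7 on the observed scale.
- **Activities**: weights and offsets from the versioned 22-entry
  catalog; offsets are scaled by 1.6 because thresholding attenuates
  them ≈0.6×, so the *observed* per-activity mean spread matches the
  catalog's. Each respondent keeps a stable habitual set of 4
  activities (Gumbel top-k by weight) used for half of the episodes in
  both waves — real respondents repeat their routines, and without this
  the test/retest reporter overlap falls to its independence floor,
  well below what field data show.
- **Episodes**: per period, 2–4 episodes of ≥5 min tiling the window
  exactly (multinomial split of the remaining minutes); wake
  N(06:00, 30 min), sleep N(22:30, 45 min).
- **Supplementary questions**: stable answer with item-specific
  prevalence; the retest answer flips with an item-specific
  probability (3-point items move to another category uniformly). For
  a balanced binary item, downstream κ = 1 − 2·flip in expectation.

What the generator does *not* emulate: period-of-day activity
structure (no circadian activity mix), companion effects on affect,
informative dropout, interviewer and recall biases, and any
correlation between demographics and time use. Passing recovery tests
therefore shows the statistics are computed correctly and the pipeline
is calibrated — not that the instrument itself is valid in the field.

## Calibration findings worth knowing

- **Attenuation**: latent-scale effects shrink by ≈0.6–0.7 after
  thresholding to a 1–3 scale. Recovered ICCs are likewise attenuated
  relative to the latent intraclass correlation; recovery tests
  therefore compare against a large-n run of the same pipeline
  (n = 30 000, where the ICC's sampling SE is ≈0.005) rather than
  against the latent value.
- **Mean–variance coupling**: on a bounded scale, demographic cells
  with lower affect sit further from the NA floor and have higher
  conditional variance. Classical OLS standard errors consequently
  understate main-effect sampling variability somewhat (the original
  analysis, also classical OLS, would share this). Recovery is
  therefore assessed against the estimator's sampling SE, estimated
  from the Monte Carlo replicates; robust errors are deliberately out
  of scope.
- **Threshold-induced non-additivity**: additive latent effects are
  not exactly additive on the observed scale, so with non-zero main
  effects the nested F correctly rejects the main-effects-only model
  at above the nominal rate — that is power against real curvature.
  Type-I calibration is checked under the exact null (all β = 0),
  where the test battery verifies the rate is near α.
- **U-index ceiling**: with conditionally independent item noise the
  generator's U-index settles slightly below typical field levels;
  matching them exactly would need correlated item errors within
  episodes, which the model intentionally omits.
- **Activity-profile stability**: with 13 ranked activities and
  realistic per-activity standard errors for the rarely reported ones,
  the between-wave correlation of mean net affect sits a little below
  0.9 in expectation at n = 1000 and well above it at n = 4000; a
  single-sample value near 0.95 carries a wide confidence interval, so
  the test battery checks the replicate mean, not one draw.

## Numerical conventions

Two-sided tests, α = 0.05 by default. Ranking ties break by activity
code for deterministic listings (Spearman itself uses average ranks, so
the statistic is unaffected). The ≥5% activity filter is inclusive and
applies to the baseline percentage only. Degenerate inputs (zero
variance, all-tied gold standard, empty categories, rank-deficient
designs) raise typed errors naming the offending quantity rather than
returning NaN. All randomness flows from a single seed through one
generator, so studies, reports and JSON summaries are byte-identical
across runs with the same seed.

## Problem sizes used in the test battery

Oracle equivalence tests run at n ≤ 30 with exhaustive enumeration;
calibration runs use 500 cohorts of n = 200 (ICC coverage), 200
replicates of n = 500 (AUC), 200 replicates of n = 800 (nested F), 300
replicates of n = 2000 against a 3 × 150 000 averaged truth
(regression recovery), and n = 1000 vs n = 30 000 for the end-to-end
ICC recovery. These sizes put Monte Carlo noise well inside each
test's tolerance while keeping the default suite fast.
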