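# Methods

## Data model

The unit of observation is the participant-fortnight ("window"). A window
carries up to three symptom scores — PHQ-9 total (0–27), GAD-7 total
(0–21), PHQ-9 item 9 (0–3, the suicidality target; any score > 0 also sets
a binary suicidal-thoughts flag) — a panic-attack count carried through as
a passthrough field, and the element-wise mean of the per-post linguistic
feature vectors published in that fortnight. A window's features are
missing exactly when it has no posts; a window's symptoms are missing when
the assessment was skipped. Post-level scores are averaged **unweighted**:
the alternative of weighting posts by word count is defensible, but the
plain arithmetic mean is the simpler reading of "window-averaged scores"
and is what the reader implements.

Severity bands (nil-minimal 0–4, mild 5–9, moderate 10–14, moderately
severe 15–19, severe 20–scale-max) partition each scale's full range; the
top band is capped at the scale maximum (27 / 21) rather than left
open-ended.

Two tabular layouts are supported: the long per-window CSV (reserved
columns plus one column per feature, blank cells = missing, per-post word
counts serialized as a `;`-joined list so round-trips are lossless) and the
wide per-participant means table. A participant enters the analysed sample
when at least one window pairs a completed assessment with a feature
vector; per-participant means use only such matched windows, and each
symptom's mean uses the matched windows where that scale was completed, so
the means table recomputes exactly from the long table. Cohort activity
summaries (assessments completed, total posts, total and per-post word
counts) report means, sample SDs (n−1) and ranges over participants; the
cohort mean of words-per-post averages the per-participant means rather
than pooling posts.

## Between-subject screening

Spearman's ρ is the Pearson correlation of midranks, computed on
pairwise-complete observations; a constant vector yields an
undefined-correlation signal (NaN), not an exception. Uncorrected two-sided
p-values use exact enumeration of all rank pairings for n ≤ 10 and the t
approximation above that. The exact path enumerates n! pairings, which at
n = 10 costs a few seconds per pair — fine for single calls, slow for a
204-pair family; screened families are expected at n > 10 where the t
approximation applies.

Family-wise error over the feature × target family is controlled by the
permutation distribution of the most extreme statistic: per permutation the
target rows are shuffled jointly across participants (preserving the mutual
association of the three symptom scales; a per-target option exists because
the alternative reading — permuting each target separately — is also
coherent, and the two differ only through the targets' mutual correlation),
every family correlation is recomputed from pre-standardized midranks by a
single matrix product, and the maximum |ρ| is recorded. Adjusted p-values
use the add-one convention (1 + #{max ≥ |ρ_obs|}) / (n_perm + 1), which can
never be exactly zero; when all n! permutations are enumerated
(`exhaustive=True`, n ≤ 8) the exact fraction #{max ≥ |ρ_obs|}/n! is
reported instead, since the identity permutation guarantees validity.
Because rank correlations take discrete values, observed and permuted
statistics are rounded to 10 decimals before ≥ comparisons so genuinely
tied permutations count as at least as extreme. The significance threshold
is the empirical (1−α) quantile of the null maxima, taken as the higher
order statistic (conservative). The permutation stage requires a complete
case matrix: rows with any missing cell are dropped with a logged count.
Recomputing pairwise-deleted ranks per pair per permutation would be
prohibitively slow at 10,000 permutations, and after the final-sample
filter the means table is complete anyway, so listwise and pairwise
deletion coincide in the intended use. Observed coefficients, uncorrected
p-values and bootstrap CIs do use pairwise deletion per pair.

Confidence intervals are percentile bootstrap over participants (default
10,000 resamples); degenerate resamples (constant vector) are redrawn and
counted.

## PLS regression

Features and targets are z-scored with the sample (n−1) SD; constant
columns are dropped with a warning. Components are extracted with SIMPLS
(de Jong 1993): at each step the dominant left singular vector of the
current feature–target cross-covariance gives the weight vector, scores
are normalized, and the covariance is deflated by the orthonormalized
feature loading. The fit is deterministic; each component's sign is fixed
so the largest-magnitude entry of its weight vector is positive.
Components are nested, with a single target the first weight vector is
proportional to the feature–target covariance, and at full rank the
coefficients equal the least-squares solution — both properties are tested
against independent oracles, and predictions cross-check against
scikit-learn's PLS implementation.

Component count is selected by k-fold (default 5) cross-validation over
participants with seeded shuffled folds. Standardization is re-fit on each
training fold and applied to its held-out fold — the leakage-free variant;
a `global_standardize` flag reproduces the single up-front z-transform for
fidelity comparisons. MSE is measured on the standardized target scale
(so the 0-component, train-fold-mean predictor has MSE ≈ 1) and pooled
over held-out cells. The stopping rule is the first local minimum: the
smallest m with mse[m+1] ≥ mse[m], else the candidate maximum (default 10,
capped by fold rank). The reported relative change is
100·(mse[selected] − mse[0])/mse[0].

Restricted models use bootstrap stability selection: participants are
resampled with replacement (default 10,000 times), the one-component
weight vector — the normalized standardized covariance X'y, which is the
first PLS direction — is recomputed per resample and sign-aligned to the
full-sample direction (without alignment the direction's sign
indeterminacy would inflate bootstrap SDs), and each feature receives
z = bootstrap mean / bootstrap SD. The k (default 4) features with the
largest |z| are selected, ties broken by feature label; resamples with a
constant target are redrawn and counted. Model quality is reported as the
Pearson correlation (and its square) between predictions and observations
per target, with a percentile-bootstrap CI over participants.

## Within-subject generalizability

The fitted group-level model (in the standard workflow, the restricted
model) predicts each participant's symptom score at every window where
both the model's features and that target's assessment exist, on the
original scale via the stored centers and scales. The predicted and
observed series are correlated over time with Pearson's r — the prediction
stage is interval-scale; a Spearman option exists — and transformed to
Fisher z = atanh(r). Participants with fewer than 3 usable windows (2
points always give |r| = 1), a constant series, or |r| = 1 (infinite z)
are excluded from aggregation and counted, never clamped: clamping would
bias the mean z, and zero intra-individual symptom variance is a real
phenomenon in sparse cohorts. For each threshold n_min in 3..18 the
analysis restricts to participants with ≥ n_min usable windows and reports
the count, mean z, t-based 95% CI and the two-sided one-sample t-test of
mean z against zero; thresholds leaving fewer than 2 participants are
marked unavailable rather than raised.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes.
Each participant draws a latent severity trait (SD 1); the window-level
mood is trait + `mood_within_sd`·N(0,1). Symptom totals are affine in the
mood — defaults PHQ-9 = 14.5 + 5·mood, GAD-7 = 11.6 + 4.2·mood, matching a
moderately-severe blogging cohort — plus occasion noise
(`symptom_noise_sd`, default 2 points), rounded and clipped to the scale
bounds. The default `mood_within_sd` of 0.4 puts the intra-individual
PHQ-9 SD near 2.8 points. Item 9 is the monotone coarsening
min(⌊PHQ-9/9⌋, 3), so total ≥ item 9 holds by construction and the implied
suicidality mean is near 1.1.

Feature j is baseline_j + loading_j · s + shared factor + noise, truncated
at zero because percent-of-words scores are non-negative (truncation is a
mild attenuation applied after the correlation structure is imposed; with
the default baselines, Gamma(2,2) ≈ 4%, it is negligible). The signal s is
`within_coupling`·mood + (1−coupling)·trait: at coupling = 1 the
within-subject feature–symptom relation equals the between-subject one
(ergodic); at 0 features are time-invariant per subject while symptoms
fluctuate (non-ergodic); both regimes share the same between-subject
structure. The default loading pattern plants four informative features
(±0.8, ±1.0) among nulls, the shared per-window factor (scale 0.4)
correlates the features, and window noise has SD 1. Gaussian features with
truncation are a modeling convenience, not a claim about real
text-analysis score distributions, which are typically skewed
zero-inflated percentages.

Missingness is independent per window: assessments deleted with
probability 0.58 (≈ 7.5 of 18 completed, as in sparse real cohorts) and
blog windows with probability 0.30 (unreported in the motivating designs;
chosen so most participants retain several matched windows). Post counts
are gamma-mixed Poisson — participant rates from Gamma(0.5, mean 1.83/
fortnight), then 1 + Poisson per present window — giving the strong
over-dispersion real posting totals show (variance ≫ mean); words per post
are likewise gamma-mixed Poisson around 192.76. `degrade_to_study_profile`
thins a complete cohort so each participant keeps an exact completion
count, reproducing a published unbalanced profile; the packaged
38-participant reference activity table provides one such profile.

What passing tests show — and don't: the generator reproduces the moments,
bounds, missingness pattern and ergodic/non-ergodic contrast the pipeline
is sensitive to, so green tests certify the statistical machinery
(error control, selection, aggregation), not that real blog language
carries these effect sizes. Real data add skewed feature distributions,
temporal autocorrelation, informative missingness and platform effects the
generator deliberately omits.

## Problem sizes and numerical choices

The validation suite runs the family-wise error simulation at 500
null cohorts × 1,000 permutations × the full 204-test family, bootstrap
selection recovery at 50 cohorts of n = 200 with 1,000 resamples, and the
ergodicity contrast at 50 paired cohorts of 50 participants using the
restricted 4-feature model at n_min = 10 — sizes at which the binomial
simulation error is well below the margins tested while the whole suite
stays desk-scale. Seeded `numpy` Generators drive all randomness; a master
seed derives per-stage seeds via `SeedSequence`. Degenerate inputs follow
one convention throughout: undefined statistics signal as NaN and are
excluded with counts, validation errors raise with the offending field
named.

## Limitations

- The permutation family uses listwise deletion (see above); severely
  unbalanced missingness in a means table would shrink the family's n.
- The exact Spearman p path is factorial in n and practical only to n = 10.
- The CV stopping rule is a first-local-minimum heuristic; a flat MSE
  curve selects 0 components even when a tiny true effect exists.
- Bootstrap stability selection assumes the one-component direction is
  meaningful; with no signal the selected set is essentially arbitrary
  (and tests verify it is unstable across seeds, as it should be).
- Within-subject aggregation treats participants' z-values as exchangeable;
  no autocorrelation correction is applied to the per-participant r.
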