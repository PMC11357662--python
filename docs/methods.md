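# Methods

This note records the statistical procedures the package implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that matter for
reproducing its output.

## Outcome classification

Each participant is reduced to the most advanced colonoscopy finding, in
severity order CRC > advanced precancerous lesion > non-advanced adenoma >
excluded-polyp-only > no finding. An adenoma is advanced if ≥1 cm, with
tubulovillous or villous components, or with high-grade dysplasia; a sessile
serrated polyp is advanced if ≥1 cm. Hyperplastic and non-defined polyps and
serrated lesions <1 cm never count as neoplasms: participants with only such
findings are excluded from both comparison groups, since their long-term
significance is unclear and leaving them among the controls would dilute the
contrast. Two deliberately conservative conventions where the classification
rules are silent: an adenoma of unknown size is non-advanced unless a
histology flag is set, and a serrated lesion ≥1 cm that is not an explicit
sessile serrated polyp is flagged with a warning and treated as
excluded-polyp-only rather than silently promoted.

Analyses contrast *any neoplasm* (CRC + advanced lesions + non-advanced
adenomas) or *advanced neoplasm* (CRC + advanced lesions) against the
no-finding group.

## Eligibility

The filter emulates an average-risk screening population: exclusion on
missing exposure information, excluded-polyp-only findings, age <50 or ≥80
(inclusion is the half-open window [50, 80)), CRC or IBD history, a
colonoscopy in the preceding five years, inadequate bowel preparation,
incomplete colonoscopy, and optionally missing genotype data — applied in
that order, each participant tallied under the first matching rule, so the
tallies plus the kept set always reconcile to the input. "Preceding five
years" is read strictly: exactly 5.0 years ago is kept (switchable).

## PRS construction and scaling

The score is Σ_j β_j g_ij with dosages oriented to each variant's effect
allele (g → 2−g when the matrix stores the other allele). Strand-ambiguous
A/T and C/G variants are retained with a warning — allele labels cannot
detect a strand flip, and dropping them silently would change the score.
Missing dosages are filled with twice the empirical effect-allele frequency
(the mean observed dosage), standard practice in score calculation; a
missing *variant* is an error by default, droppable on request.

Percentiles use mid-ranks against a reference sample: the percentile of x
is 100·r/(R+1) with r = #(ref<x) + (#(ref=x)+1)/2, so queries outside the
reference range stay strictly inside (0, 100) and the reference's
self-transform is uniform to within KS < 0.02 at R ≈ 2500. Tertile cut
points are the 1/3 and 2/3 inverted-CDF quantiles of the reference with
right-closed intervals, which splits a distinct-valued reference of size 3k
exactly k/k/k. The default reference is the no-finding group (the scale on
which tertiles are defined); a whole-cohort reference is available, and the
calibration experiments use it because the generator's truth is defined on
the full-sample percentile scale.

## Logistic models

All fits are maximum likelihood (Newton), tolerance 1e-8 on the coefficient
update, at most 50 iterations. Categorical covariates are dummy-coded
against their first-listed category; the exposure reference is ≤1 time/week
and the tertile reference T1. Non-convergence or |β|>15 raises a separation
error carrying diagnostics instead of returning silently unstable output.
Confidence intervals are Wald (exp(β ± 1.96·SE)) throughout;
profile-likelihood intervals are not implemented. The per-tertile trend
enters the tertile as an ordinal 1/2/3 term; the joint analysis fits the
six-level exposure × tertile cross-classification in one model with the
unexposed/T1 cell as uni-reference (empty cells are flagged and returned
NaN). Interaction is tested on the cross-product term(s), Wald by default
with a likelihood-ratio option.

## Multiple imputation

Chained equations over the categorical covariates: each incomplete variable
is regressed on all others — multinomial logistic for nominal variables,
proportional-odds for declared-ordinal ones (falling back to multinomial if
the ordinal fit fails) — and imputations are drawn from the fitted category
probabilities, sweeping the variables (least-missing first) for a fixed
number of cycles. Parameter uncertainty is propagated by fitting each
imputation model on a bootstrap resample of the observed rows, a
proper-imputation variant that avoids explicit posterior draws. Defaults
are m = 5 completed datasets and 10 cycles — the conventional defaults for
chained-equations software — with weak regularisation (C = 100) so
near-deterministic relationships in the observed data survive into the
imputations. Variables with no observed values or ≥50% missingness are
refused.

Downstream fits are pooled by Rubin's rules: Q̄ the mean estimate, W the
mean within-imputation variance, B the between-imputation variance,
T = W + (1+1/m)B, with Barnard–Rubin degrees of freedom when the
complete-data degrees of freedom are supplied. Descriptive tables are
complete-case (their printed denominators exclude the missing); model
estimates may use either complete-case or pooled-imputation data.

## Descriptive table and the chi-square dialect

Group comparisons use the Pearson chi-square on complete-case counts.
Tables with more than 1 degree of freedom are uncorrected. 2×2 tables get a
*capped* continuity correction: the per-cell correction term is
min(0.5, |O−E|), never more than the deviation itself, so the statistic
cannot be over-corrected past zero — two groups with near-identical
proportions give statistic 0 and p = 1 exactly, where a plain Yates
subtraction would manufacture a spurious statistic. This dialect reproduces
every four-decimal p-value of the published descriptive table the package
validates against, including the p = 1.0000 row that plain Yates cannot
produce. Percentages print to one decimal, half-up, over the full group
totals (the published convention), while the tests use complete-case
counts; the hormone-replacement row is tested among women only. The
comparison behind the published age row (median/IQR) is not named in the
source material and is reported descriptively only.

## The genetic risk equivalent

GRE = b_E/b_P from one jointly fitted model, so Cov(b_E, b_P) is available;
fitting the two coefficients in separate models is refused. The default
interval is the delta method,

Var(G) = V_E/b_P² + b_E²·V_P/b_P⁴ − 2·b_E·C/b_P³,

chosen because it is the construction consistent with the symmetric
published intervals this package validates its arithmetic against. Fieller
intervals (roots of the usual quadratic in G, flagged unbounded when the
denominator is not significantly nonzero) and a participant-resampling
bootstrap (default 2000 resamples, percentile interval) are provided
because the ratio's sampling distribution is skewed when b_P is weakly
identified; delta and Fieller agree to within ~10% relative width once
|b_P|/SE(b_P) > 5. The point estimate is refused when |b_P| < 1e-8. A GRE
is computed even when the exposure association is not significant — the
result is flagged rather than suppressed, since a null-compatible numerator
is information, not an error. Sign convention: a protective exposure with a
risk-increasing score gives a negative GRE ("risk compensated for").

Scale equivariance holds by construction: re-expressing the PRS term on a
c-times-finer scale divides the GRE by c, so percentile vs
fraction-of-distribution parameterisations are interchangeable.

## Synthetic cohorts

The generator draws per-variant allele frequencies uniformly over
(0.1, 0.9), hard-call dosages Binomial(2, f) under Hardy–Weinberg, and
emits 30% of variants as continuous dosages (hard call plus small truncated
Gaussian jitter) to emulate imputed loci; weights are Normal(0, 0.08) on
the log-odds scale, typical GWAS effect sizes. Covariates are drawn from
categorical marginals calibrated to a German screening-colonoscopy
population's no-finding group (e.g. 56/44 female/male, smoking 52/36/12);
they are realistic noise, with all covariate effects zero unless requested.
The exposure prevalence defaults to 0.767 and the outcome is drawn from the
additive logit model with b_E = 0.2 and b_P = 0.0105 per percentile
(true GRE ≈ 19, the regime the package's motivating application sits in),
the intercept solved by bisection on the realised sample to a marginal
prevalence of 0.464 (tolerance 1e-4). Cases subdivide into advanced
lesions (target fraction 0.39, tilted by percentile and exposure, intercept
again solved by bisection) and CRC among the advanced (6.5%). Findings
lists are generated to be *classified*, not labelled: the stored outcome
class is always the classifier's output on the generated findings.
Hyperplastic-only participants (4% of non-cases) and planted ineligibility
flags give the filter stage real work. Covariate missingness is injected
after outcome generation, missing at random given outcome and sex (cases
×1.3, women ×1.1 on the base rates, which default to the missingness
pattern of the motivating descriptive table); the exposure itself is
missing completely at random (2%).

One seed drives everything; per-component generators are derived
deterministically from it, so output is byte-identical across runs. The
generator's true GRE (b_E/b_P) is stored in the output metadata for
recovery tests.

What the generator does **not** emulate — and therefore what passing tests
cannot certify about real data: linkage disequilibrium and population
structure (variants are independent), genotyping batch effects, confounded
exposures (covariate effects default to zero; recovery experiments measure
estimator calibration, not confounding control), informative missingness
beyond the outcome/sex tilt, and misreported diet.

## Calibration experiments

`prsgre.experiments` re-runs the full pipeline on fresh cohorts:
closed-form agreement of the 2×2 logistic MLE to <1e-6 over 1000 random
tables; parameter recovery at n = 5000 over 200 replicates (mean b̂_E and
b̂_P within 5% of truth; delta-method GRE interval coverage 93–97%);
interaction type-I error within (0.03, 0.07) over 1000 additive replicates
at n = 2000; and percentile-uniformity of the reference transform
(KS < 0.02 at R = 2559). The replicate counts and sample sizes are the
package's chosen experiment scale: large enough that the Monte-Carlo error
of each summary sits well inside the asserted bands, small enough to re-run
routinely.

## Known limitations

No genotype imputation, liftover or per-variant QC beyond allele matching;
no survival/incidence modelling (the design is cross-sectional prevalence);
no dose–response modelling beyond the three-level intake split; no
multiple-testing adjustment across descriptive rows; the proportional-odds
imputation model assumes parallel log-odds across category thresholds; and
the published adjusted odds ratios themselves cannot be recomputed here
because the underlying participant-level data are not public — the package
validates against the published summary arithmetic and recovers known
truths on synthetic cohorts instead.
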