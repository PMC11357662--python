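# prsgre

Polygenic risk scores, gene–environment logistic models and **genetic risk
equivalents** for screening-colonoscopy cohorts.

## The problem

Screening colonoscopy studies relate lifestyle exposures (here: red and
processed meat intake, dichotomised at >1 time/week) and polygenic risk to
the prevalence of colorectal neoplasms — colorectal cancer (CRC), advanced
precancerous lesions, and non-advanced adenomas — against participants with
no finding. Communicating how a modifiable exposure compares with inherited
risk is hard; the **genetic risk equivalent (GRE)** expresses an exposure's
adjusted effect as the number of PRS percentiles conferring the same change
in log-odds.

With a weighted polygenic risk score over risk loci,

```
PRS_i = Σ_j β_j g_ij          (g_ij = effect-allele dosage ∈ [0, 2])
```

scaled to percentiles of a reference population (by default the no-finding
group), and one jointly fitted logistic model

```
logit P(neoplasm) = α + b_E·E + b_P·percentile(PRS) + Σ_k γ_k C_k ,
```

the GRE is the coefficient ratio

```
GRE = b_E / b_P     (PRS percentiles)
```

with delta-method, Fieller or bootstrap confidence intervals. A GRE of 30
means avoiding the exposure is equivalent to a 30-percentile lower
polygenic score.

The package implements the whole pipeline: scoring-file/dosage/VCF I/O, PRS
construction with allele orientation, reference percentile and tertile
scaling, most-advanced-finding outcome classification, screening-eligibility
filtering with an exclusion flowchart, chained-equations multiple imputation
with Rubin pooling, adjusted logistic models (exposure, PRS tertile/trend,
uni-reference joint grids, interaction tests), the GRE itself, and a
synthetic-cohort generator with a known gene–environment truth so every
stage is testable without patient data.

## Worked example

```python
from prsgre import SimulationConfig, simulate_cohort, apply_exclusions
from prsgre.models import ModelSpec, add_prs_scales, fit_logistic
from prsgre.gre import compute_gre, gre_report

cfg = SimulationConfig(n_participants=5000, b_E=0.2, b_P=0.0105, seed=42)
sim = simulate_cohort(cfg)                      # true GRE = 0.2 / 0.0105 ≈ 19.0
result = apply_exclusions(sim.phenotypes, require_genotyped=True)
print({k: v for k, v in result.tallies.items() if v})
print("kept:", result.n_kept, "of", result.n_input)

data = add_prs_scales(result.kept, reference="cohort")
spec = ModelSpec(outcome="any_neoplasm", exposure="processed_meat",
                 covariates=("age", "sex"), prs_term="percentile")
fit = fit_logistic(spec, data)
gre = compute_gre(fit, method="delta")
gre.label = "any neoplasm"
print(gre_report([gre]))
print("true GRE:", round(sim.metadata["true_gre"], 1))
```

prints

```
{'missing_meat_info': 104, 'polyp_only_finding': 100, 'age_out_of_range': 47,
 'crc_or_ibd_history': 19, 'recent_colonoscopy': 50,
 'inadequate_bowel_prep': 21, 'incomplete_colonoscopy': 24}
kept: 4635 of 5000
Comparison                   OR (95% CI)            GRE (95% CI)
--------------------------------------------------------------------------
any neoplasm                 1.22 (1.06, 1.40)      20.8 (5.7, 35.9)
true GRE: 19.0
```

The exclusion tally is the study flowchart: participants lacking exposure
data, carrying only hyperplastic/non-defined polyps, outside ages 50–79,
with CRC/IBD history, a colonoscopy within five years, or an inadequate or
incomplete examination are removed in that order. On the eligible cohort the
exposed group's adjusted odds ratio is 1.22, and that risk increase is
equivalent to a 20.8-percentile higher PRS (95% CI 5.7–35.9) — close to the
generating truth of 19.0.

The same pipeline is available from the shell:

```bash
prsgre simulate --n 5000 --seed 42 --out cohort/
prsgre filter --pheno cohort/phenotypes.csv --out kept.csv --flowchart flow.txt
prsgre fit --pheno kept.csv --prs-reference cohort --out fit.json
prsgre gre --fit fit.json
```

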