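"""Synthetic screening-colonoscopy cohorts with a known gene-environment truth.

The generator emulates the data structure the analysis assumes: per-variant
genotype dosages with a scoring file, Table-1-style categorical covariates, a
binary dietary exposure (processed meat > 1 time/week), and a colonoscopy
outcome drawn from a logistic model

    logit P(neoplasm_i) = alpha + b_E * E_i + b_P * percentile(PRS_i)
                          + sum_k gamma_k * C_ik ,

with the intercept alpha solved by bisection so the marginal prevalence
matches the requested baseline. Cases are subdivided into advanced and
non-advanced lesions (CRC among the advanced), findings lists are emitted so
the classification stage has real work, a configurable fraction of
participants carry hyperplastic-only findings or ineligibility flags for the
filter stage, and covariate missingness is injected missing-at-random given
outcome and sex. The generator's true genetic risk equivalent is b_E / b_P
by construction and is stored in the output metadata for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from . import cohort as ch
from .exceptions import ConfigurationError
from .prs import GenotypeMatrix, ReferencePercentiler, VariantWeight, compute_prs

# Default categorical covariate marginals, calibrated to the no-finding group
# of a German screening-colonoscopy population (realistic fixtures, not a
# reproduction of any cohort). Reference level listed first.
DEFAULT_COVARIATE_DISTRIBUTIONS: dict[str, dict[str, float]] = {
    "sex": {"Female": 0.561, "Male": 0.439},
    "education": {"<10": 0.511, "10-11": 0.260, ">11": 0.229},
    "bmi": {"<25": 0.383, "25-<30": 0.416, ">=30": 0.201},
    "smoking": {"Never": 0.516, "Former": 0.364, "Current": 0.120},
    "alcohol": {"None": 0.263, "Low": 0.389, "Low-moderate": 0.202,
                "Moderate-high": 0.115, "High": 0.031},
    "physical_activity": {">=30 min/day": 0.971, "<30 min/day": 0.029},
    "hrt": {"No": 0.620, "Yes": 0.380},  # drawn for female participants only
    "diabetes": {"No": 0.913, "Yes": 0.087},
    "family_history_crc": {"No": 0.880, "Yes": 0.120},
    "nsaids": {"No": 0.819, "Yes": 0.181},
    "history_colonoscopy": {"No": 0.678, "Yes": 0.322},
    "whole_grain": {">=1/day": 0.427, "<1/day": 0.573},
    "fruit": {">=1/day": 0.619, "<1/day": 0.381},
    "vegetable": {">=1/day": 0.538, "<1/day": 0.462},
    "poultry": {">=1/week": 0.595, "<1/week": 0.405},
    "red_meat": {"<=1/week": 0.466, ">1/week": 0.534},
}

MEAT_LEVELS = ("<=1/week", ">1/week")

_ALLELE_PAIRS = (("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"))


def _default_advanced_model() -> dict[str, float]:
    return {"target_fraction": 0.39, "per_percentile": 0.006,
            "per_exposure": 0.05, "crc_fraction": 0.065}


def _default_missingness() -> dict[str, float]:
    return {"education": 0.010, "bmi": 0.016, "smoking": 0.010,
            "alcohol": 0.038, "physical_activity": 0.014, "hrt": 0.015,
            "diabetes": 0.006, "nsaids": 0.071, "whole_grain": 0.016,
            "fruit": 0.004, "vegetable": 0.002, "poultry": 0.016}


def _default_ineligibility() -> dict[str, float]:
    return {"age_out_of_range": 0.010, "crc_or_ibd_history": 0.005,
            "recent_colonoscopy": 0.010, "inadequate_bowel_prep": 0.005,
            "incomplete_colonoscopy": 0.005, "not_genotyped": 0.0}


@dataclass
class SimulationConfig:
    """Study conditions for one simulated cohort.

    ``b_E`` is the exposure log-odds ratio (processed meat > 1 time/week),
    ``b_P`` the log-odds ratio per PRS percentile; their ratio is the
    generator's true genetic risk equivalent. ``covariate_effects`` maps
    ``"column=level"`` keys to log-odds contributions (all zero by default:
    covariates are realistic noise, not confounders, unless requested).
    """

    n_participants: int = 5000
    n_variants: int = 140
    allele_freq_range: tuple[float, float] = (0.1, 0.9)
    weight_scale: float = 0.08
    imputed_fraction: float = 0.3
    b_E: float = 0.2
    b_P: float = 0.0105
    covariate_effects: dict[str, float] = field(default_factory=dict)
    baseline_prevalence: float = 0.464
    exposure_prevalence: float = 0.767
    advanced_fraction_model: dict[str, float] = field(
        default_factory=_default_advanced_model)
    missingness_rates: dict[str, float] = field(default_factory=_default_missingness)
    polyp_only_fraction: float = 0.04
    ineligibility_rates: dict[str, float] = field(default_factory=_default_ineligibility)
    meat_missing_rate: float = 0.02
    covariate_distributions: dict[str, dict[str, float]] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_participants <= 0 or self.n_variants <= 0:
            raise ConfigurationError(
                "n_participants and n_variants must be positive")
        lo, hi = self.allele_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigurationError(
                f"allele frequencies must lie in (0, 1): {self.allele_freq_range}")
        for name, p in [("baseline_prevalence", self.baseline_prevalence),
                        ("exposure_prevalence", self.exposure_prevalence),
                        ("imputed_fraction", self.imputed_fraction),
                        ("polyp_only_fraction", self.polyp_only_fraction),
                        ("meat_missing_rate", self.meat_missing_rate),
                        *self.missingness_rates.items(),
                        *self.ineligibility_rates.items()]:
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be a probability, got {p}")

    def distributions(self) -> dict[str, dict[str, float]]:
        dists = dict(DEFAULT_COVARIATE_DISTRIBUTIONS)
        if self.covariate_distributions:
            dists.update(self.covariate_distributions)
        return dists


@dataclass
class CohortSimulation:
    """A simulated cohort: phenotypes, genotypes, weights and ground truth."""

    phenotypes: pd.DataFrame
    genotypes: GenotypeMatrix
    weights: list[VariantWeight]
    config: SimulationConfig
    metadata: dict


def _subrng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def _solve_intercept(lp: np.ndarray, target: float, tol: float = 1e-4,
                     what: str = "prevalence") -> float:
    """Bisection for alpha so that mean(expit(alpha + lp)) == target."""
    if not (0.0 < target < 1.0):
        raise ConfigurationError(
            f"target {what} must lie strictly in (0, 1), got {target}")
    lo, hi = -40.0, 40.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if float(np.mean(expit(mid + lp))) < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12:
            break
    mid = 0.5 * (lo + hi)
    if abs(float(np.mean(expit(mid + lp))) - target) > tol:
        raise ConfigurationError(f"could not solve intercept for {what} {target}")
    return mid


def simulate_genotypes(config: SimulationConfig) -> tuple[GenotypeMatrix, list[VariantWeight]]:
    """Dosage matrix plus scoring weights under Hardy-Weinberg per variant.

    Per-variant allele frequencies are uniform over ``allele_freq_range`` and
    hard-call dosages are Binomial(2, f). A fraction ``imputed_fraction`` of
    variants is emitted as continuous dosages (hard call plus small truncated
    Gaussian jitter) to emulate imputed loci. Weights are Normal(0,
    weight_scale) on the log-odds scale, oriented so the matrix counts the
    effect allele. Only strand-unambiguous allele pairs are generated.
    """
    rng = _subrng(config.seed, 1)
    n, m = config.n_participants, config.n_variants
    lo, hi = config.allele_freq_range
    freqs = rng.uniform(lo, hi, size=m)
    dosages = rng.binomial(2, freqs, size=(n, m)).astype(float)
    n_imp = int(round(config.imputed_fraction * m))
    if n_imp:
        cols = rng.choice(m, size=n_imp, replace=False)
        jitter = rng.normal(0.0, 0.08, size=(n, n_imp))
        dosages[:, cols] = np.clip(dosages[:, cols] + jitter, 0.0, 2.0)
    pair_idx = rng.integers(len(_ALLELE_PAIRS), size=m)
    weights, alleles = [], {}
    for j in range(m):
        vid = f"rs{j + 1:06d}"
        eff, oth = _ALLELE_PAIRS[pair_idx[j]]
        w = float(rng.normal(0.0, config.weight_scale))
        weights.append(VariantWeight(vid, eff, oth, w))
        alleles[vid] = (eff, oth)
    ids = [f"P{i + 1:06d}" for i in range(n)]
    genotypes = GenotypeMatrix(ids, [w.variant_id for w in weights], dosages,
                               counted_alleles=alleles)
    return genotypes, weights


def _draw_categoricals(config: SimulationConfig, rng: np.random.Generator,
                       n: int) -> pd.DataFrame:
    cols = {}
    for name, dist in config.distributions().items():
        levels = list(dist)
        probs = np.asarray(list(dist.values()), float)
        probs = probs / probs.sum()
        draw = rng.choice(len(levels), size=n, p=probs)
        cols[name] = pd.Categorical.from_codes(draw, categories=levels)
    df = pd.DataFrame(cols)
    # Hormone replacement history is defined for women only.
    df.loc[df["sex"].astype(str) == "Male", "hrt"] = np.nan
    return df


def _covariate_lp(config: SimulationConfig, cov: pd.DataFrame) -> np.ndarray:
    lp = np.zeros(len(cov))
    for key, beta in config.covariate_effects.items():
        col, _, level = key.partition("=")
        if col not in cov.columns:
            raise ConfigurationError(f"covariate effect on unknown column {col!r}")
        lp += beta * (cov[col].astype(str) == level).to_numpy(float)
    return lp


def _make_findings(rng, kind, exposure_pct=None):
    """A findings list consistent with the requested outcome class."""
    if kind == ch.NO_FINDING:
        return []
    if kind == ch.POLYP_ONLY:
        return [{"kind": "hyperplastic_polyp",
                 "size_cm": round(float(rng.uniform(0.2, 0.8)), 2)}]
    if kind == ch.NON_ADVANCED:
        return [{"kind": "adenoma",
                 "size_cm": round(float(rng.uniform(0.2, 0.9)), 2)}]
    if kind == ch.ADVANCED:
        u = rng.random()
        if u < 0.6:
            f = {"kind": "adenoma", "size_cm": round(float(rng.uniform(1.0, 3.0)), 2)}
        elif u < 0.9:
            f = {"kind": "adenoma", "size_cm": round(float(rng.uniform(0.3, 0.9)), 2),
                 "tubulovillous_or_villous": bool(rng.random() < 0.7),
                 "high_grade_dysplasia": bool(rng.random() < 0.4)}
            if not (f["tubulovillous_or_villous"] or f["high_grade_dysplasia"]):
                f["tubulovillous_or_villous"] = True
        else:
            f = {"kind": "sessile_serrated_polyp",
                 "size_cm": round(float(rng.uniform(1.0, 2.5)), 2)}
        out = [f]
    else:  # CRC
        out = [{"kind": "CRC", "size_cm": round(float(rng.uniform(2.0, 6.0)), 2)}]
    if rng.random() < 0.3:  # synchronous small lesion, exercises the severity order
        out.append({"kind": "adenoma",
                    "size_cm": round(float(rng.uniform(0.2, 0.9)), 2)})
    return out


def simulate_cohort(config: SimulationConfig) -> CohortSimulation:
    """Generate a full cohort; see the module docstring for the model."""
    n = config.n_participants
    genotypes, weights = simulate_genotypes(config)
    prs = compute_prs(genotypes, weights)
    pct = ReferencePercentiler().fit(prs).transform(prs)

    cov = _draw_categoricals(config, _subrng(config.seed, 2), n)
    rng_exp = _subrng(config.seed, 3)
    exposed = rng_exp.random(n) < config.exposure_prevalence
    lp = (config.b_E * exposed.astype(float) + config.b_P * pct
          + _covariate_lp(config, cov))
    alpha = _solve_intercept(lp, config.baseline_prevalence)
    rng_out = _subrng(config.seed, 4)
    case = rng_out.random(n) < expit(alpha + lp)

    afm = config.advanced_fraction_model
    adv_lp = (afm["per_percentile"] * (pct - 50.0)
              + afm["per_exposure"] * exposed.astype(float))
    advanced = np.zeros(n, dtype=bool)
    a0 = 0.0
    rng_adv = _subrng(config.seed, 5)
    if case.any():
        a0 = _solve_intercept(adv_lp[case], afm["target_fraction"],
                              what="advanced fraction")
        advanced[case] = rng_adv.random(int(case.sum())) < expit(a0 + adv_lp[case])
    crc = np.zeros(n, dtype=bool)
    crc[advanced] = rng_adv.random(int(advanced.sum())) < afm["crc_fraction"]

    rng_find = _subrng(config.seed, 6)
    polyp_only = ~case & (rng_find.random(n) < config.polyp_only_fraction)
    target_class = np.where(
        crc, ch.CRC, np.where(advanced, ch.ADVANCED,
        np.where(case, ch.NON_ADVANCED,
        np.where(polyp_only, ch.POLYP_ONLY, ch.NO_FINDING))))
    findings = [_make_findings(rng_find, k) for k in target_class]
    outcome = [ch.classify_finding(f).value for f in findings]

    rng_elig = _subrng(config.seed, 7)
    inel = config.ineligibility_rates
    age = rng_elig.integers(50, 80, size=n)
    bad_age = rng_elig.random(n) < inel.get("age_out_of_range", 0.0)
    age[bad_age] = np.where(rng_elig.random(int(bad_age.sum())) < 0.5,
                            rng_elig.integers(45, 50, size=int(bad_age.sum())),
                            rng_elig.integers(80, 85, size=int(bad_age.sum())))
    hist_flag = rng_elig.random(n) < inel.get("crc_or_ibd_history", 0.0)
    history_crc = hist_flag & (rng_elig.random(n) < 0.5)
    history_ibd = hist_flag & ~history_crc
    had_colo = cov["history_colonoscopy"].astype(str).to_numpy() == "Yes"
    last_colo = np.where(had_colo, rng_elig.uniform(5.0, 15.0, size=n), np.nan)
    recent = rng_elig.random(n) < inel.get("recent_colonoscopy", 0.0)
    last_colo[recent] = rng_elig.uniform(0.0, 5.0, size=int(recent.sum()))
    cov.loc[recent, "history_colonoscopy"] = "Yes"
    prep_ok = rng_elig.random(n) >= inel.get("inadequate_bowel_prep", 0.0)
    coecum = rng_elig.random(n) >= inel.get("incomplete_colonoscopy", 0.0)
    genotyped = rng_elig.random(n) >= inel.get("not_genotyped", 0.0)
    meat_complete = rng_elig.random(n) >= config.meat_missing_rate

    df = pd.DataFrame({"participant_id": genotypes.participant_ids})
    df["age"] = age
    df = pd.concat([df, cov], axis=1)
    proc = pd.Categorical.from_codes(exposed.astype(int), categories=list(MEAT_LEVELS))
    df["processed_meat"] = proc
    df["processed_meat_gt1pw"] = exposed.astype(float)
    df.loc[~meat_complete, ["processed_meat", "red_meat"]] = np.nan
    df.loc[~meat_complete, "processed_meat_gt1pw"] = np.nan
    df["meat_info_complete"] = meat_complete
    df["history_crc"] = history_crc
    df["history_ibd"] = history_ibd
    df["last_colonoscopy_years_ago"] = last_colo
    df["bowel_prep_adequate"] = prep_ok
    df["coecum_reached"] = coecum
    df["genotyped"] = genotyped
    df["prs"] = prs
    df["prs_percentile"] = pct
    df["findings"] = findings
    df["outcome_class"] = outcome
    df = pd.concat([df, ch.outcome_flags(df["outcome_class"])], axis=1)

    # Missing-at-random given outcome and sex: cases and women answer the
    # questionnaire items slightly less completely.
    rng_miss = _subrng(config.seed, 8)
    is_case = df["any_neoplasm"].to_numpy(bool)
    is_female = cov["sex"].astype(str).to_numpy() == "Female"
    mask = pd.DataFrame(False, index=df.index,
                        columns=list(config.missingness_rates))
    for col, rate in config.missingness_rates.items():
        p = np.clip(rate * np.where(is_case, 1.3, 1.0)
                    * np.where(is_female, 1.1, 1.0), 0.0, 0.95)
        hit = rng_miss.random(n) < p
        if col == "hrt":
            hit &= is_female
        df.loc[hit, col] = np.nan
        mask[col] = hit

    metadata = {
        "true_gre": config.b_E / config.b_P if config.b_P != 0 else np.nan,
        "alpha": alpha,
        "advanced_intercept": a0,
        "percentile_reference": "cohort",
        "missingness_mask": mask,
    }
    return CohortSimulation(df, genotypes, weights, replace(config), metadata)
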