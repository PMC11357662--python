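"""Calibration experiments: parameter recovery, interval coverage, type-I error.

These run the whole pipeline on freshly generated synthetic cohorts and
summarise how well it recovers the generating truth. They are the package's
evidence that the estimator chain (simulation -> eligibility filter ->
logistic fit -> ratio statistic) is unbiased and correctly calibrated at
realistic sample sizes, and they back the reproducibility script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import apply_exclusions
from .gre import compute_gre
from .models import ModelSpec, fit_logistic, interaction_test
from .simulate import SimulationConfig, simulate_cohort

_JOINT_SPEC = ModelSpec(exposure="processed_meat", covariates=(),
                        prs_term="percentile")


def _rep_seed(seed: int, rep: int) -> int:
    return int(np.random.SeedSequence([int(seed), rep]).generate_state(1)[0]
               % 2 ** 31)


def parameter_recovery(n_replicates: int = 200, n_participants: int = 5000,
                       b_E: float = 0.2, b_P: float = 0.0105,
                       seed: int = 7) -> dict:
    """Recover (b_E, b_P) and the true GRE over replicate cohorts.

    Each replicate generates a cohort under the stated effects, applies the
    eligibility filter, fits the joint exposure + PRS-percentile model and
    computes the delta-method GRE interval. Reports the mean estimates and
    the empirical coverage of the nominal 95% interval for the true GRE
    b_E / b_P.
    """
    true_gre = b_E / b_P
    b_E_hat, b_P_hat, gre_hat, covered = [], [], [], []
    for rep in range(n_replicates):
        cfg = SimulationConfig(n_participants=n_participants, b_E=b_E,
                               b_P=b_P, seed=_rep_seed(seed, rep))
        kept = apply_exclusions(simulate_cohort(cfg).phenotypes,
                                require_genotyped=True).kept
        res = compute_gre(fit_logistic(_JOINT_SPEC, kept))
        b_E_hat.append(res.b_E)
        b_P_hat.append(res.b_P)
        gre_hat.append(res.gre)
        covered.append(res.ci_low <= true_gre <= res.ci_high)
    return {
        "n_replicates": n_replicates, "n_participants": n_participants,
        "true_b_E": b_E, "true_b_P": b_P, "true_gre": true_gre,
        "mean_b_E": float(np.mean(b_E_hat)),
        "mean_b_P": float(np.mean(b_P_hat)),
        "mean_gre": float(np.mean(gre_hat)),
        "ci_coverage": float(np.mean(covered)),
    }


def interaction_type1_error(n_replicates: int = 1000,
                            n_participants: int = 2000,
                            alpha: float = 0.05, seed: int = 11) -> dict:
    """Rejection rate of the interaction Wald test under an additive truth.

    Cohorts are generated with main effects only (the default generator is
    additive on the logit scale), so rejections of the exposure x percentile
    cross-product are type-I errors.
    """
    rejections = 0
    for rep in range(n_replicates):
        cfg = SimulationConfig(n_participants=n_participants,
                               seed=_rep_seed(seed, rep))
        kept = apply_exclusions(simulate_cohort(cfg).phenotypes).kept
        p = interaction_test(_JOINT_SPEC, kept)["p_value"]
        rejections += p < alpha
    return {"n_replicates": n_replicates, "n_participants": n_participants,
            "alpha": alpha, "rejection_rate": rejections / n_replicates}


def closed_form_2x2_check(n_tables: int = 1000, seed: int = 3,
                          cell_range: tuple[int, int] = (5, 60)) -> dict:
    """Maximum deviation of the logistic MLE from the closed-form 2x2 log-OR."""
    rng = np.random.default_rng(seed)
    spec = ModelSpec(exposure="E", covariates=(), prs_term=None)
    worst = 0.0
    for _ in range(n_tables):
        a, b, c, d = rng.integers(cell_range[0], cell_range[1] + 1, size=4)
        rows = ([("non_advanced_adenoma", 1.0)] * a + [("no_finding", 1.0)] * b
                + [("non_advanced_adenoma", 0.0)] * c
                + [("no_finding", 0.0)] * d)
        df = pd.DataFrame(rows, columns=["outcome_class", "E"])
        fit = fit_logistic(spec, df)
        worst = max(worst, abs(float(fit.params["E"]) - np.log(a * d / (b * c))))
    return {"n_tables": n_tables, "max_abs_error": float(worst)}


def reference_uniformity(n_reference: int = 2559, seed: int = 5) -> dict:
    """KS distance of the reference's self-percentiles from uniformity."""
    from scipy import stats

    from .prs import percentile_transform

    ref = np.random.default_rng(seed).normal(size=n_reference)
    pct = percentile_transform(ref, ref)
    ks = float(stats.kstest(pct / 100.0, "uniform").statistic)
    return {"n_reference": n_reference, "ks_statistic": ks}
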