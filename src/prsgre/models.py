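"""Logistic models for exposure, PRS and joint gene-environment effects.

All models contrast an outcome group (any neoplasm, or advanced neoplasm)
against participants with no finding, by maximum-likelihood logistic
regression (Newton/IRLS, tolerance 1e-8 on the coefficient change, at most
50 iterations). Categorical covariates enter dummy-coded against their
first-listed level; the dietary exposure's reference is <=1 time/week and
the PRS tertile reference is T1. The exposure and per-percentile PRS
coefficients fitted jointly here are the inputs of the genetic risk
equivalent (see :mod:`prsgre.gre`), which needs their covariance — hence
fits return the full coefficient covariance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import cohort as ch
from .exceptions import ConfigurationError, EmptyCellWarning, SeparationError
from .prs import ReferencePercentiler, TertileAssigner

OUTCOME_GROUPS = {
    "any_neoplasm": ch.ANY_NEOPLASM,
    "advanced_neoplasm": ch.ADVANCED_NEOPLASM,
}

#: The full Table-2-style adjustment set used on synthetic cohorts.
FULL_ADJUSTMENT = (
    "age", "sex", "education", "smoking", "bmi", "physical_activity",
    "alcohol", "hrt", "diabetes", "nsaids", "family_history_crc",
    "history_colonoscopy", "whole_grain", "fruit", "vegetable", "poultry",
)
MINIMAL_ADJUSTMENT = ("age", "sex")

PRS_TERM_FORMS = (None, "percentile", "tertile", "tertile_ordinal")


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: outcome contrast, exposure, adjustments and PRS form."""

    outcome: str = "any_neoplasm"
    exposure: str | None = "processed_meat"
    covariates: tuple[str, ...] = MINIMAL_ADJUSTMENT
    prs_term: str | None = None
    interaction: bool = False

    def __post_init__(self):
        if self.outcome not in OUTCOME_GROUPS:
            raise ConfigurationError(f"unknown outcome {self.outcome!r}")
        if self.prs_term not in PRS_TERM_FORMS:
            raise ConfigurationError(f"unknown PRS term form {self.prs_term!r}")
        if self.exposure is not None and self.exposure in self.covariates:
            raise ConfigurationError(
                f"exposure {self.exposure!r} also appears in the adjustment set")
        if self.interaction and (self.exposure is None or self.prs_term is None):
            raise ConfigurationError(
                "interaction requires both an exposure and a PRS term")


@dataclass
class ModelFit:
    """Coefficients, covariance and metadata from one logistic fit."""

    params: pd.Series
    cov: pd.DataFrame
    converged: bool
    n: int
    llf: float
    spec: ModelSpec | None = None
    term_columns: dict[str, list[str]] = field(default_factory=dict)

    def se(self, column: str) -> float:
        return float(np.sqrt(self.cov.loc[column, column]))


def add_prs_scales(data: pd.DataFrame, reference: str = "no_finding") -> pd.DataFrame:
    """Attach percentile / tertile columns for the PRS on a reference scale.

    ``reference="no_finding"`` (default) scales against participants with no
    finding at colonoscopy; ``reference="cohort"`` uses everyone. Returns a
    copy with ``prs_percentile``, ``prs_tertile`` and ``prs_tertile_code``.
    """
    if reference == "no_finding":
        ref = data.loc[data["outcome_class"].eq(ch.NO_FINDING), "prs"].to_numpy()
    elif reference == "cohort":
        ref = data["prs"].to_numpy()
    else:
        raise ConfigurationError(f"unknown PRS reference {reference!r}")
    out = data.copy()
    out["prs_percentile"] = ReferencePercentiler().fit(ref).transform(out["prs"])
    ta = TertileAssigner().fit(ref)
    out["prs_tertile"] = pd.Categorical(ta.transform(out["prs"]),
                                        categories=list(ta.labels))
    out["prs_tertile_code"] = ta.transform_codes(out["prs"])
    return out


def _encode_column(data: pd.DataFrame, col: str) -> pd.DataFrame:
    s = data[col]
    if isinstance(s.dtype, pd.CategoricalDtype):
        levels = [lv for lv in s.cat.categories if lv in set(s.dropna().unique())]
    elif s.dtype == object:
        levels = sorted(s.dropna().unique())
    else:
        return pd.DataFrame({col: s.astype(float)})
    out = {}
    for lv in levels[1:]:  # first-listed level is the reference
        out[f"{col}[{lv}]"] = s.eq(lv).astype(float)
    if not out:
        raise ConfigurationError(f"column {col!r} has a single observed level")
    return pd.DataFrame(out, index=data.index)


def _prs_columns(data: pd.DataFrame, form: str) -> pd.DataFrame:
    if form == "percentile":
        return pd.DataFrame({"prs_percentile": data["prs_percentile"].astype(float)})
    if form == "tertile":
        return _encode_column(data, "prs_tertile")
    if form == "tertile_ordinal":
        return pd.DataFrame({"prs_tertile_code":
                             data["prs_tertile_code"].astype(float)})
    raise ConfigurationError(f"unknown PRS term form {form!r}")


def build_design(spec: ModelSpec, data: pd.DataFrame):
    """Design matrix, response and term->columns map for one model."""
    keep = data["outcome_class"].isin(OUTCOME_GROUPS[spec.outcome]) \
        | data["outcome_class"].eq(ch.NO_FINDING)
    df = data.loc[keep]
    blocks, terms = [], {}
    if spec.exposure is not None:
        b = _encode_column(df, spec.exposure)
        blocks.append(b)
        terms["exposure"] = list(b.columns)
    if spec.prs_term is not None:
        b = _prs_columns(df, spec.prs_term)
        blocks.append(b)
        terms["prs"] = list(b.columns)
    for cov in spec.covariates:
        b = _encode_column(df, cov)
        blocks.append(b)
        terms[cov] = list(b.columns)
    if spec.interaction:
        prod = {}
        for ec in terms["exposure"]:
            for pc in terms["prs"]:
                prod[f"{ec}:{pc}"] = blocks[0][ec] * blocks[1][pc]
        b = pd.DataFrame(prod, index=df.index)
        blocks.append(b)
        terms["interaction"] = list(b.columns)
    X = pd.concat(blocks, axis=1) if blocks else pd.DataFrame(index=df.index)
    y = df["outcome_class"].isin(OUTCOME_GROUPS[spec.outcome]).astype(float)
    complete = X.notna().all(axis=1)
    X, y = X.loc[complete], y.loc[complete]
    X.insert(0, "const", 1.0)
    return X, y, terms


def fit_logistic(spec: ModelSpec, data: pd.DataFrame) -> ModelFit:
    """Maximum-likelihood logistic fit for one model specification.

    Raises :class:`SeparationError` on non-convergence or diverging
    coefficients (|beta| > 15, the signature of quasi-complete separation).
    """
    X, y, terms = build_design(spec, data)
    model = sm.Logit(y.to_numpy(), X.to_numpy())
    try:
        res = model.fit(method="newton", tol=1e-8, maxiter=50, disp=0)
    except Exception as exc:  # singular Hessian, perfect separation, ...
        raise SeparationError(f"logistic fit failed: {exc}",
                              {"exception": repr(exc)}) from exc
    params = pd.Series(res.params, index=X.columns)
    if not res.mle_retvals.get("converged", False):
        raise SeparationError("logistic fit did not converge in 50 iterations",
                              {"params": params.to_dict()})
    slopes = params.drop("const")
    if len(slopes) and float(np.abs(slopes).max()) > 15:
        raise SeparationError(
            "diverging coefficients suggest (quasi-)complete separation",
            {"params": params.to_dict()})
    cov = pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns)
    return ModelFit(params=params, cov=cov, converged=True, n=int(len(y)),
                    llf=float(res.llf), spec=spec, term_columns=terms)


def or_with_ci(fit: ModelFit, term: str, z: float = 1.96):
    """Odds ratio exp(beta) with the Wald 95% interval exp(beta +/- z*SE)."""
    if term in fit.term_columns and len(fit.term_columns[term]) == 1:
        term = fit.term_columns[term][0]
    if term not in fit.params.index:
        raise KeyError(f"term {term!r} not in fit "
                       f"(have {list(fit.params.index)})")
    b, se = float(fit.params[term]), fit.se(term)
    return float(np.exp(b)), float(np.exp(b - z * se)), float(np.exp(b + z * se))


def per_tertile_trend(spec: ModelSpec, data: pd.DataFrame) -> ModelFit:
    """The per-tertile trend model: tertile entered as ordinal 1/2/3."""
    return fit_logistic(replace(spec, prs_term="tertile_ordinal"), data)


def interaction_test(spec: ModelSpec, data: pd.DataFrame,
                     method: str = "wald") -> dict:
    """Test the exposure x PRS cross-product term(s).

    Wald (default): chi-square on the product coefficients with their joint
    covariance. ``method="lrt"`` compares the log-likelihoods with and
    without the cross-product.
    """
    spec_int = replace(spec, interaction=True)
    fit1 = fit_logistic(spec_int, data)
    cols = fit1.term_columns["interaction"]
    k = len(cols)
    if method == "wald":
        theta = fit1.params[cols].to_numpy()
        V = fit1.cov.loc[cols, cols].to_numpy()
        stat = float(theta @ np.linalg.solve(V, theta))
    elif method == "lrt":
        fit0 = fit_logistic(replace(spec, interaction=False), data)
        stat = float(2.0 * (fit1.llf - fit0.llf))
    else:
        raise ConfigurationError(f"unknown interaction test {method!r}")
    p = float(stats.chi2.sf(stat, k))
    return {"statistic": stat, "df": k, "p_value": p, "method": method,
            "fit": fit1}


def joint_or_table(spec: ModelSpec, data: pd.DataFrame) -> pd.DataFrame:
    """Uni-reference joint exposure x PRS-tertile odds-ratio grid.

    The six-level cross-classification enters one model with the unexposed /
    lowest-tertile cell as the common reference (OR = 1 by construction).
    Empty cells are flagged with :class:`EmptyCellWarning` and returned NaN.
    """
    import warnings

    keep = data["outcome_class"].isin(OUTCOME_GROUPS[spec.outcome]) \
        | data["outcome_class"].eq(ch.NO_FINDING)
    df = data.loc[keep].copy()
    exp_s = df[spec.exposure]
    if isinstance(exp_s.dtype, pd.CategoricalDtype):
        exp_levels = list(exp_s.cat.categories)
    else:
        exp_levels = sorted(exp_s.dropna().unique())
    tert_levels = list(TertileAssigner.labels)
    combo = exp_s.astype(str) + "|" + df["prs_tertile"].astype(str)
    combo[exp_s.isna() | df["prs_tertile"].isna()] = np.nan
    cells = [f"{e}|{t}" for e in exp_levels for t in tert_levels]
    empty = [c for c in cells if not combo.eq(c).any()]
    if empty:
        warnings.warn(f"empty joint cells: {empty}", EmptyCellWarning,
                      stacklevel=2)
    df["joint_cell"] = pd.Categorical(combo, categories=cells)
    joint_spec = ModelSpec(outcome=spec.outcome, exposure="joint_cell",
                           covariates=spec.covariates, prs_term=None)
    fit = fit_logistic(joint_spec, df)
    rows = []
    for e in exp_levels:
        for t in tert_levels:
            cell = f"{e}|{t}"
            if cell == cells[0]:
                rows.append((e, t, 1.0, np.nan, np.nan))
            elif cell in empty:
                rows.append((e, t, np.nan, np.nan, np.nan))
            else:
                orr, lo, hi = or_with_ci(fit, f"joint_cell[{cell}]")
                rows.append((e, t, orr, lo, hi))
    out = pd.DataFrame(rows, columns=[spec.exposure, "prs_tertile", "OR",
                                      "ci_low", "ci_high"])
    out.attrs["fit"] = fit
    return out
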