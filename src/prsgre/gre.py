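"""The genetic risk equivalent: an exposure's effect in PRS percentiles.

The genetic risk equivalent (GRE) translates an exposure's adjusted log-odds
ratio into the number of PRS percentiles conferring the same log-odds
change:

    GRE = b_E / b_P ,

where b_E is the exposure coefficient and b_P the per-percentile PRS
coefficient from one jointly fitted logistic model. A GRE of 30 means that
avoiding the exposure has an effect equivalent to a 30-percentile lower
polygenic score; a protective exposure paired with a risk-increasing score
yields a negative GRE (risk "compensated for"). The metric descends from
the risk/rate advancement period, which expresses an exposure's effect in
years of age rather than percentiles of genetic risk.

Both coefficients must come from the *same* fit so that their sampling
covariance is available; confidence intervals are delta-method Wald by
default, with Fieller and bootstrap alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .models import ModelFit, fit_logistic

_MIN_DENOM = 1e-8


@dataclass
class GREResult:
    """Point estimate and interval for one exposure-vs-PRS comparison."""

    gre: float
    ci_low: float
    ci_high: float
    method: str
    b_E: float
    b_P: float
    var_E: float
    var_P: float
    cov_EP: float
    exposure_term: str
    percentile_term: str
    exposure_significant: bool
    unbounded: bool = False
    label: str = ""


def _resolve(fit: ModelFit, term: str, role: str) -> str:
    if term in fit.term_columns and len(fit.term_columns[term]) == 1:
        return fit.term_columns[term][0]
    if term in fit.params.index:
        return term
    raise KeyError(f"{role} term {term!r} not found in the fitted model")


def compute_gre(fit: ModelFit, exposure_term: str = "exposure",
                percentile_term: str = "prs", method: str = "delta",
                z: float = 1.96, data: pd.DataFrame | None = None,
                n_boot: int = 2000, seed: int | None = None) -> GREResult:
    """GRE = b_E / b_P with a 95% confidence interval.

    Methods
    -------
    ``delta``
        Wald interval from the first-order variance of the ratio,
        Var(G) = V_E/b_P^2 + b_E^2 V_P/b_P^4 - 2 b_E C/b_P^3.
    ``fieller``
        Roots of the Fieller quadratic in G; when the denominator is not
        significantly nonzero the interval is unbounded and flagged.
    ``bootstrap``
        Percentile interval from refitting the same model specification on
        ``n_boot`` participant resamples (requires ``data``).
    """
    e_col = _resolve(fit, exposure_term, "exposure")
    p_col = _resolve(fit, percentile_term, "PRS percentile")
    b_E = float(fit.params[e_col])
    b_P = float(fit.params[p_col])
    V_E = float(fit.cov.loc[e_col, e_col])
    V_P = float(fit.cov.loc[p_col, p_col])
    C = float(fit.cov.loc[e_col, p_col])
    if abs(b_P) < _MIN_DENOM and method in ("delta", "bootstrap"):
        raise ConfigurationError(
            f"|b_P| = {abs(b_P):.2e} below {_MIN_DENOM}: the coefficient "
            "ratio is unstable; use the Fieller interval")
    significant = abs(b_E) > z * np.sqrt(V_E)
    common = dict(b_E=b_E, b_P=b_P, var_E=V_E, var_P=V_P, cov_EP=C,
                  exposure_term=e_col, percentile_term=p_col,
                  exposure_significant=bool(significant))

    if method == "delta":
        G = b_E / b_P
        var_G = (V_E / b_P ** 2 + b_E ** 2 * V_P / b_P ** 4
                 - 2.0 * b_E * C / b_P ** 3)
        half = z * np.sqrt(max(var_G, 0.0))
        return GREResult(gre=G, ci_low=G - half, ci_high=G + half,
                         method="delta", **common)

    if method == "fieller":
        G = b_E / b_P if abs(b_P) >= _MIN_DENOM else np.nan
        a = b_P ** 2 - z ** 2 * V_P
        b = -2.0 * (b_E * b_P - z ** 2 * C)
        c = b_E ** 2 - z ** 2 * V_E
        disc = b ** 2 - 4.0 * a * c
        if a <= 0 or disc < 0:
            # Denominator not significantly nonzero: interval is the whole
            # line (or its complement); report unbounded.
            return GREResult(gre=G, ci_low=-np.inf, ci_high=np.inf,
                             method="fieller", unbounded=True, **common)
        r = np.sqrt(disc)
        lo, hi = sorted(((-b - r) / (2 * a), (-b + r) / (2 * a)))
        return GREResult(gre=G, ci_low=float(lo), ci_high=float(hi),
                         method="fieller", **common)

    if method == "bootstrap":
        if data is None or fit.spec is None:
            raise ConfigurationError(
                "bootstrap needs the original data and the fit's ModelSpec")
        rng = np.random.default_rng(seed)
        G = b_E / b_P
        draws = []
        n = len(data)
        while len(draws) < n_boot:
            boot = data.iloc[rng.integers(n, size=n)]
            try:
                bfit = fit_logistic(fit.spec, boot)
            except Exception:
                continue  # resample produced a degenerate fit
            bb_E = float(bfit.params[e_col])
            bb_P = float(bfit.params[p_col])
            if abs(bb_P) >= _MIN_DENOM:
                draws.append(bb_E / bb_P)
        lo, hi = np.percentile(draws, [2.5, 97.5])
        return GREResult(gre=G, ci_low=float(lo), ci_high=float(hi),
                         method="bootstrap", **common)

    raise ConfigurationError(f"unknown GRE method {method!r}")


def gre_report(results: list[GREResult]) -> str:
    """Render GRE results as a fixed-width table, one decimal as printed.

    Odds ratios show two decimals, GREs one; a non-significant exposure is
    marked so the reader knows the ratio rests on a null-compatible
    numerator.
    """
    header = f"{'Comparison':<28} {'OR (95% CI)':<22} {'GRE (95% CI)':<22}"
    lines = [header, "-" * len(header)]
    for r in results:
        orr = np.exp(r.b_E)
        olo = np.exp(r.b_E - 1.96 * np.sqrt(r.var_E))
        ohi = np.exp(r.b_E + 1.96 * np.sqrt(r.var_E))
        or_s = f"{orr:.2f} ({olo:.2f}, {ohi:.2f})"
        if r.unbounded:
            gre_s = f"{r.gre:.1f} (unbounded)"
        else:
            gre_s = f"{r.gre:.1f} ({r.ci_low:.1f}, {r.ci_high:.1f})"
        if not r.exposure_significant:
            gre_s += " *"
        label = r.label or r.exposure_term
        lines.append(f"{label:<28} {or_s:<22} {gre_s:<22}")
    if any(not r.exposure_significant for r in results):
        lines.append("* exposure association not significant at the 5% level")
    return "\n".join(lines)
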