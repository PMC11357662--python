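"""Multiple imputation by chained equations for categorical covariates,
with Rubin's-rules pooling of downstream model estimates.

Each incomplete variable is regressed on all other variables (multinomial
logistic for nominal variables, proportional-odds for ordinal ones), the
imputations are drawn from the fitted category probabilities, and the
variables are cycled a fixed number of times. Parameter uncertainty is
propagated by fitting each imputation model on a bootstrap resample of the
observed rows (a proper-imputation variant), so the m completed datasets
genuinely differ where the data are uninformative.

Downstream, a model is fitted once per completed dataset and the m fits are
pooled: Qbar is the mean estimate, W the mean within-imputation variance,
B the between-imputation variance, T = W + (1 + 1/m) B, with Barnard-Rubin
degrees of freedom for the t-based interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression

from .exceptions import ConfigurationError
from .models import ModelFit, ModelSpec, fit_logistic


@dataclass
class ImputationSet:
    """m completed copies of a covariate table plus the imputed-cell mask."""

    datasets: list[pd.DataFrame]
    mask: pd.DataFrame
    m: int
    seed: int | None = None

    def __post_init__(self):
        if self.m < 2:
            raise ConfigurationError("multiple imputation needs m >= 2")
        if len(self.datasets) != self.m:
            raise ConfigurationError("len(datasets) != m")


class ChainedEquationsImputer(BaseEstimator):
    """Multiply impute missing categorical covariates by chained equations.

    Parameters
    ----------
    variables : columns to impute; defaults to every column with a missing
        value. Each must be categorical (nominal or ordinal) and less than
        half missing.
    m : number of completed datasets (default 5).
    n_cycles : chained-equation sweeps per dataset (default 10).
    ordinal : variable names whose categories are ordered; these get a
        proportional-odds imputation model instead of a multinomial one.
    C : inverse regularisation of the imputation models. Weak by default so
        near-deterministic relationships in the observed data survive into
        the imputations.
    """

    def __init__(self, variables=None, m=5, n_cycles=10, ordinal=(),
                 C=100.0, random_state=None):
        self.variables = variables
        self.m = m
        self.n_cycles = n_cycles
        self.ordinal = ordinal
        self.C = C
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None):
        variables = list(self.variables) if self.variables is not None \
            else [c for c in X.columns if X[c].isna().any()]
        for v in variables:
            n_obs = X[v].notna().sum()
            if n_obs == 0:
                raise ConfigurationError(f"{v!r} has no observed values")
            frac = 1.0 - n_obs / len(X)
            if frac >= 0.5:
                raise ConfigurationError(
                    f"{v!r} is {frac:.0%} missing; refusing to impute")
        self.variables_ = variables
        return self

    def fit_transform(self, X: pd.DataFrame, y=None) -> ImputationSet:
        self.fit(X)
        rng = np.random.default_rng(self.random_state)
        mask = X[self.variables_].isna() if self.variables_ \
            else pd.DataFrame(index=X.index)
        datasets = [self._complete_once(X, rng) for _ in range(self.m)]
        return ImputationSet(datasets=datasets, mask=mask, m=self.m,
                             seed=self.random_state)

    # -- one chained-equations pass ------------------------------------

    def _complete_once(self, X: pd.DataFrame, rng) -> pd.DataFrame:
        df = X.copy()
        miss = {v: X[v].isna().to_numpy() for v in self.variables_}
        # Initialise by sampling from each variable's observed values.
        for v in self.variables_:
            obs = df.loc[~miss[v], v].to_numpy()
            df.loc[miss[v], v] = rng.choice(obs, size=int(miss[v].sum()))
        order = sorted(self.variables_, key=lambda v: miss[v].sum())
        for _ in range(self.n_cycles):
            for v in order:
                if not miss[v].any():
                    continue
                self._impute_variable(df, X, v, miss[v], rng)
        return df

    def _predictors(self, df: pd.DataFrame, target: str) -> pd.DataFrame:
        cols = [c for c in df.columns if c != target]
        blocks = []
        for c in cols:
            s = df[c]
            if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) \
                    or s.dtype == bool:
                blocks.append(pd.get_dummies(s.astype(str), prefix=c,
                                             drop_first=True, dtype=float))
            else:
                blocks.append(s.astype(float).to_frame(c))
        return pd.concat(blocks, axis=1)

    def _impute_variable(self, df, X, v, miss, rng):
        Z = self._predictors(df, v)
        y_obs = df.loc[~miss, v].astype(str)
        levels = sorted(y_obs.unique())
        if len(levels) < 2:
            return  # nothing to model; keep the initial draws
        # Bootstrap the observed rows so the model parameters are a draw,
        # not a point estimate (proper imputation).
        idx = rng.choice(np.flatnonzero(~miss), size=int((~miss).sum()),
                         replace=True)
        Zb, yb = Z.iloc[idx], df[v].astype(str).iloc[idx]
        if len(set(yb)) < 2:
            return
        if v in self.ordinal and len(levels) > 2:
            probs, classes = self._ordinal_probs(Zb, yb, Z.loc[miss], levels)
        else:
            clf = LogisticRegression(C=self.C, max_iter=500)
            clf.fit(Zb.to_numpy(), yb.to_numpy())
            probs = clf.predict_proba(Z.loc[miss].to_numpy())
            classes = clf.classes_
        u = rng.random((probs.shape[0], 1))
        pick = (probs.cumsum(axis=1) < u).sum(axis=1).clip(0, len(classes) - 1)
        df.loc[miss, v] = np.asarray(classes, dtype=object)[pick]

    def _ordinal_probs(self, Zb, yb, Zmiss, levels):
        """Proportional-odds model; falls back to multinomial on failure."""
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        try:
            codes = pd.Categorical(yb, categories=levels, ordered=True)
            mod = OrderedModel(codes.codes.astype(float), Zb.to_numpy(),
                               distr="logit")
            res = mod.fit(method="bfgs", maxiter=200, disp=0)
            if not np.all(np.isfinite(res.params)):
                raise RuntimeError("non-finite proportional-odds fit")
            probs = res.model.predict(res.params, exog=Zmiss.to_numpy())
            return np.asarray(probs), np.asarray(levels, dtype=object)
        except Exception:
            clf = LogisticRegression(C=self.C, max_iter=500)
            clf.fit(Zb.to_numpy(), yb.to_numpy())
            return clf.predict_proba(Zmiss.to_numpy()), clf.classes_


def impute(table: pd.DataFrame, variables=None, m: int = 5,
           seed: int | None = None, **kwargs) -> ImputationSet:
    """Multiply impute ``table``; see :class:`ChainedEquationsImputer`."""
    imp = ChainedEquationsImputer(variables=variables, m=m,
                                  random_state=seed, **kwargs)
    return imp.fit_transform(table)


@dataclass
class PooledEstimate:
    """One coefficient pooled over m imputations by Rubin's rules."""

    term: str
    estimate: float          # Qbar
    within: float            # W
    between: float           # B
    total: float             # T = W + (1 + 1/m) B
    df: float                # Barnard-Rubin degrees of freedom
    m: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total))

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        t = stats.t.ppf(0.5 + level / 2, self.df) if np.isfinite(self.df) \
            else stats.norm.ppf(0.5 + level / 2)
        return self.estimate - t * self.se, self.estimate + t * self.se


def pool(fits: list[ModelFit], n_complete_df: float | None = None) -> pd.DataFrame:
    """Pool per-imputation fits into one table of Rubin's-rules estimates.

    All fits must share the same coefficient layout. ``n_complete_df`` is the
    complete-data residual degrees of freedom (n - k); when given, the
    Barnard-Rubin small-sample adjustment is applied, otherwise the
    large-sample degrees of freedom are used.
    """
    if len(fits) < 2:
        raise ConfigurationError("pooling needs at least two fits")
    layout = list(fits[0].params.index)
    for f in fits[1:]:
        if list(f.params.index) != layout:
            raise ConfigurationError("fits have mismatched coefficient layouts")
    m = len(fits)
    est = np.column_stack([f.params.to_numpy() for f in fits])
    var = np.column_stack([np.diag(f.cov.to_numpy()) for f in fits])
    Qbar = est.mean(axis=1)
    W = var.mean(axis=1)
    B = est.var(axis=1, ddof=1)
    T = W + (1.0 + 1.0 / m) * B
    rows = []
    for i, term in enumerate(layout):
        if B[i] > 0:
            r = (1.0 + 1.0 / m) * B[i] / W[i]
            df_large = (m - 1) * (1.0 + 1.0 / r) ** 2
            if n_complete_df is not None:
                lam = (1.0 + 1.0 / m) * B[i] / T[i]
                df_obs = ((n_complete_df + 1.0) / (n_complete_df + 3.0)
                          * n_complete_df * (1.0 - lam))
                df = 1.0 / (1.0 / df_large + 1.0 / df_obs)
            else:
                df = df_large
        else:
            df = np.inf
        pe = PooledEstimate(term=term, estimate=float(Qbar[i]),
                            within=float(W[i]), between=float(B[i]),
                            total=float(T[i]), df=float(df), m=m)
        lo, hi = pe.ci()
        rows.append((term, pe.estimate, pe.se, pe.within, pe.between,
                     pe.total, pe.df, lo, hi))
    return pd.DataFrame(rows, columns=["term", "estimate", "se", "within",
                                       "between", "total", "df", "ci_low",
                                       "ci_high"]).set_index("term")


def fit_pooled(spec: ModelSpec, data: pd.DataFrame, imputations: ImputationSet,
               ) -> pd.DataFrame:
    """Fit ``spec`` on each completed dataset and pool by Rubin's rules.

    ``data`` supplies the non-imputed analysis columns (outcome, exposure,
    PRS terms); each completed covariate table overrides its columns.
    """
    fits = []
    for completed in imputations.datasets:
        merged = data.copy()
        for col in completed.columns:
            merged[col] = completed[col].to_numpy()
        fits.append(fit_logistic(spec, merged))
    k = len(fits[0].params)
    return pool(fits, n_complete_df=float(fits[0].n - k))
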