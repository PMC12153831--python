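"""CPUE standardization with a Gaussian generalized additive model.

The response is log(CPUE + 1); candidate predictors enter as univariate
penalized B-spline smooths in a fixed order — year, month, longitude,
latitude, SST, Chl-a, SSS, SSH. Collinearity is screened first with
variance inflation factors (VIF_k = 1/(1 - R²_k), reject at 5); terms are
then added forward in the fixed order, keeping each one only if it lowers
the AIC, so the accepted path has strictly decreasing AIC by construction.

The penalized fit itself delegates to statsmodels' GLMGam (Gaussian family,
identity link) — a standard routine; the scientific content here is the
model specification, screening and selection logic, and the partial-effect
extraction used to read off covariate responses (e.g. the thermal optimum
window on the SST smooth).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.gam.api import BSplines, GLMGam

#: candidate smooth terms, in the fixed nesting order of the selection path
DEFAULT_TERMS = ("year", "month", "lon", "lat", "sst", "chla", "sss", "ssh")


@dataclass
class GamSpec:
    """Model specification: term order, basis dimensions, penalty weights.

    ``df`` is the B-spline basis dimension per term (default 10; 5 for year,
    whose handful of levels cannot support more); bases are clamped at
    runtime to the number of distinct covariate values. ``alpha`` is the
    quadratic penalty weight (one shared default; per-term via dict).
    """

    terms: tuple = DEFAULT_TERMS
    response: str = "cpue"  # log1p applied internally
    df: dict = field(default_factory=lambda: {"year": 5})
    df_default: int = 10
    degree: int = 3
    alpha: float | dict = 1.0

    def df_for(self, term: str, n_unique: int) -> int:
        want = self.df.get(term, self.df_default)
        return int(max(self.degree + 1, min(want, n_unique - 1)))

    def alpha_for(self, term: str) -> float:
        if isinstance(self.alpha, dict):
            return float(self.alpha.get(term, 1.0))
        return float(self.alpha)


@dataclass
class GamResult:
    """A fitted model: fit statistics, per-term table, partial effects."""

    terms: tuple
    aic: float
    r2: float
    deviance_explained_pct: float
    n: int
    term_table: pd.DataFrame  # term, edf, chi2, p
    partials: dict  # term -> DataFrame(x, effect, se, lo95, hi95)
    formula: str

    def partial_effect(self, term: str) -> pd.DataFrame:
        return self.partials[term]


def vif_screen(table: pd.DataFrame, columns=None, threshold: float = 5.0) -> pd.DataFrame:
    """Variance inflation factors of each covariate on the others.

    VIF_k = 1/(1 - R²_k) where R²_k is from an OLS of covariate k on the
    remaining covariates plus an intercept. A perfectly collinear covariate
    reports ``inf`` and fails. Columns: covariate, vif, passed.
    """
    cols = list(columns) if columns is not None else list(table.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 covariates for VIF")
    x = table[cols].to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("covariates contain non-finite values")
    if x.shape[0] <= len(cols):
        raise ValueError("need more observations than covariates")
    rows = []
    for k, name in enumerate(cols):
        others = np.delete(x, k, axis=1)
        exog = sm.add_constant(others)
        res = sm.OLS(x[:, k], exog).fit()
        r2 = min(res.rsquared, 1.0)
        vif = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        rows.append({"covariate": name, "vif": float(vif), "passed": bool(vif < threshold)})
    return pd.DataFrame(rows)


def _formula(terms) -> str:
    if not terms:
        return "log(CPUE + 1) ~ 1"
    return "log(CPUE + 1) ~ " + " + ".join(f"s({t})" for t in terms)


def _fit(y, data: pd.DataFrame, terms, spec: GamSpec):
    """Penalized fit for one term set; returns (results, smoother or None)."""
    if not terms:
        model = sm.GLM(y, np.ones((y.size, 1)), family=sm.families.Gaussian())
        return model.fit(), None
    x = data[list(terms)].to_numpy(dtype=float)
    dfs = [spec.df_for(t, data[t].nunique()) for t in terms]
    smoother = BSplines(
        x, df=dfs, degree=[spec.degree] * len(terms), include_intercept=False,
        variable_names=list(terms),
    )
    alphas = [spec.alpha_for(t) for t in terms]
    model = GLMGam(
        y, exog=np.ones((y.size, 1)), smoother=smoother, alpha=alphas,
        family=sm.families.Gaussian(),
    )
    return model.fit(), smoother


def _term_slices(smoother, n_exog: int = 1):
    """Column slice of the design matrix for each smooth term."""
    out = {}
    start = n_exog
    for sm_k in smoother.smoothers:
        width = sm_k.basis.shape[1]
        out[sm_k.variable_name] = slice(start, start + width)
        start += width
    return out


def _edf_by_term(results, slices) -> dict:
    """Effective degrees of freedom per term from the hat-matrix diagonal."""
    edf = getattr(results, "edf", None)
    if edf is None:
        return {t: float(s.stop - s.start) for t, s in slices.items()}
    edf = np.asarray(edf, dtype=float)
    return {t: float(edf[s].sum()) for t, s in slices.items()}


def fit_gam(data: pd.DataFrame, spec: GamSpec | None = None, terms=None) -> GamResult:
    """Fit log(CPUE+1) against the requested smooth terms.

    Reports AIC, R², percent deviance explained, a per-term table with
    effective degrees of freedom and a Wald chi-square significance test,
    and mean-centered partial-effect curves with 95% bands evaluated at the
    observed covariate values.
    """
    spec = spec or GamSpec()
    terms = tuple(spec.terms if terms is None else terms)
    missing = [t for t in terms if t not in data.columns]
    if missing:
        raise ValueError(f"records missing covariate column(s): {missing}")
    y = np.log1p(data[spec.response].to_numpy(dtype=float))
    if not np.isfinite(y).all():
        raise ValueError("non-finite response after log(CPUE + 1)")

    results, smoother = _fit(y, data, terms, spec)
    resid = y - results.fittedvalues
    tss = float(((y - y.mean()) ** 2).sum())
    rss = float((resid**2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    dev_pct = 100.0 * r2

    term_rows = []
    partials = {}
    if smoother is not None:
        slices = _term_slices(smoother)
        edfs = _edf_by_term(results, slices)
        cov = np.asarray(results.cov_params())
        params = np.asarray(results.params)
        for t in terms:
            sl = slices[t]
            b = params[sl]
            v = cov[sl, sl]
            try:
                chi2 = float(b @ np.linalg.pinv(v) @ b)
            except np.linalg.LinAlgError:  # pragma: no cover
                chi2 = np.nan
            dof = max(edfs[t], 1.0)
            p = float(stats.chi2.sf(chi2, dof)) if np.isfinite(chi2) else np.nan
            term_rows.append({"term": t, "edf": edfs[t], "chi2": chi2, "p": p})

            basis = smoother.smoothers[terms.index(t)].basis
            f = basis @ b
            se = np.sqrt(np.maximum((basis @ v * basis).sum(axis=1), 0.0))
            xv = data[t].to_numpy(dtype=float)
            order = np.argsort(xv, kind="stable")
            centered = f - f.mean()
            partials[t] = pd.DataFrame(
                {
                    "x": xv[order],
                    "effect": centered[order],
                    "se": se[order],
                    "lo95": centered[order] - 1.96 * se[order],
                    "hi95": centered[order] + 1.96 * se[order],
                }
            ).drop_duplicates(subset="x").reset_index(drop=True)

    return GamResult(
        terms=terms,
        aic=float(results.aic),
        r2=r2,
        deviance_explained_pct=dev_pct,
        n=int(y.size),
        term_table=pd.DataFrame(term_rows, columns=["term", "edf", "chi2", "p"]),
        partials=partials,
        formula=_formula(terms),
    )


def stepwise_select(data: pd.DataFrame, spec: GamSpec | None = None) -> tuple:
    """Forward selection in the fixed term order, accepting AIC improvements.

    Returns ``(path, final)`` where ``path`` is a table with one row per
    candidate step (formula, aic, r2, deviance_explained_pct, accepted) and
    ``final`` is the GamResult of the selected model. AIC is strictly
    decreasing along the accepted rows.
    """
    spec = spec or GamSpec()
    current: list = []
    base = fit_gam(data, spec, terms=current)
    best_aic = base.aic
    rows = [
        {
            "formula": base.formula, "aic": base.aic, "r2": base.r2,
            "deviance_explained_pct": base.deviance_explained_pct, "accepted": True,
        }
    ]
    final = base
    for t in spec.terms:
        cand = fit_gam(data, spec, terms=current + [t])
        accept = cand.aic < best_aic
        rows.append(
            {
                "formula": cand.formula, "aic": cand.aic, "r2": cand.r2,
                "deviance_explained_pct": cand.deviance_explained_pct,
                "accepted": accept,
            }
        )
        if accept:
            current.append(t)
            best_aic = cand.aic
            final = cand
    return pd.DataFrame(rows), final


def sst_optimum_window(result: GamResult, drop: float = 0.05) -> tuple:
    """Covariate interval where the fitted SST effect stays within ``drop``
    of its maximum — the thermal window the smooth identifies as optimal."""
    pe = result.partial_effect("sst")
    span = pe["effect"].max() - pe["effect"].min()
    keep = pe["effect"] >= pe["effect"].max() - drop * max(span, 1e-12)
    xs = pe.loc[keep, "x"]
    return (float(xs.min()), float(xs.max()))
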