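"""Ordinary least squares on ln-ln axes.

A power law y = a * x^b is linear after log transformation,
ln(y) = ln(a) + b*ln(x), so plain OLS on log-log axes estimates the
allometric exponent b directly.  This is used both to pick the better
of two candidate predictors (ITD vs body length, on species means) and
for the per-species intraspecific fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["OLSFit", "LogLogOLS", "fit_ols_loglog", "compare_predictors"]


@dataclass(frozen=True)
class OLSFit:
    """OLS fit of ln(y) = alpha + beta*ln(x) with its test statistics.

    ``alpha`` is the ln-scale intercept; ``beta`` the allometric
    exponent.  ``f_stat`` tests beta = 0 on (df1, df2) = (1, n - 2)
    degrees of freedom.
    """

    alpha: float
    alpha_se: float
    beta: float
    beta_se: float
    f_stat: float
    df1: int
    df2: int
    r2: float
    adj_r2: float
    p_value: float
    n: int

    def predict(self, x) -> np.ndarray:
        """Point prediction on the original (y) scale."""
        x = np.asarray(x, dtype=float)
        if np.any(x <= 0):
            raise ValueError("predictor values must be positive")
        return np.exp(self.alpha + self.beta * np.log(x))


class LogLogOLS:
    """Estimator-style wrapper: ``fit(x, y)`` then ``predict(x)``.

    Parameters are none; fitted state lives in ``result_`` (an
    :class:`OLSFit`).  Kept deliberately tiny -- the heavy lifting is
    statsmodels' OLS.
    """

    def fit(self, x, y) -> "LogLogOLS":
        self.result_ = fit_ols_loglog(x, y)
        return self

    def predict(self, x) -> np.ndarray:
        return self.result_.predict(x)

    def get_params(self, deep: bool = True) -> dict:
        return {}

    def set_params(self, **params) -> "LogLogOLS":
        if params:
            raise ValueError(f"LogLogOLS has no parameters, got {params}")
        return self


def fit_ols_loglog(x, y) -> OLSFit:
    """Least-squares ln(y) ~ ln(x); inputs are positive original-scale values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError(f"need >= 3 points, got {len(x)}")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("all x and y must be positive (log scale)")
    lx, ly = np.log(x), np.log(y)
    if np.ptp(lx) == 0:
        raise ValueError("zero variance in x: slope is not identifiable")
    model = sm.OLS(ly, sm.add_constant(lx)).fit()
    # guard against a numerically-degenerate (perfect) fit where the F
    # statistic overflows; statsmodels then reports inf, which we keep.
    return OLSFit(
        alpha=float(model.params[0]),
        alpha_se=float(model.bse[0]),
        beta=float(model.params[1]),
        beta_se=float(model.bse[1]),
        f_stat=float(model.fvalue),
        df1=int(model.df_model),
        df2=int(model.df_resid),
        r2=float(model.rsquared),
        adj_r2=float(model.rsquared_adj),
        p_value=float(model.f_pvalue),
        n=len(x),
    )


def compare_predictors(data: pd.DataFrame) -> pd.DataFrame:
    """Rank candidate body-size predictors on species-mean values.

    For each predictor (ITD and body length) the table reports the
    Pearson correlation between species-mean ln(predictor) and
    species-mean ln(dry weight), and the R^2 of the corresponding
    log-log OLS, plus the cross-correlation between the two predictors.
    Species lacking either measurement are dropped listwise.
    """
    needed = {"species", "itd_mm", "body_length_mm", "dry_weight_mg"}
    missing = needed - set(data.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    sub = data.dropna(subset=list(needed - {"species"}))
    means = (
        sub.assign(
            ln_itd=np.log(sub["itd_mm"]),
            ln_bl=np.log(sub["body_length_mm"]),
            ln_w=np.log(sub["dry_weight_mg"]),
        )
        .groupby("species")[["ln_itd", "ln_bl", "ln_w"]]
        .mean()
    )
    if len(means) < 3:
        raise ValueError(f"need >= 3 species with both predictors, got {len(means)}")

    rows = {}
    for label, col in (("itd_mm", "ln_itd"), ("body_length_mm", "ln_bl")):
        r = float(np.corrcoef(means[col], means["ln_w"])[0, 1])
        fit = fit_ols_loglog(np.exp(means[col]), np.exp(means["ln_w"]))
        rows[label] = {"pearson_r": r, "ols_r2": fit.r2, "ols_adj_r2": fit.adj_r2,
                       "beta": fit.beta, "n_species": len(means)}
    out = pd.DataFrame(rows).T
    out.attrs["predictor_cross_r"] = float(
        np.corrcoef(means["ln_itd"], means["ln_bl"])[0, 1]
    )
    return out
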