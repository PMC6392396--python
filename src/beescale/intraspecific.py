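"""Within-species allometry and sample-size adequacy.

The interspecific power law does not necessarily hold within a species:
per-species, per-sex OLS on ln-ln axes quantifies how much of the
within-species dry-weight variation ITD actually explains.  The
resampling curve answers the companion design question -- how many
specimens must be measured before a species' mean trait value
stabilizes within the full-sample 95% confidence band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ols import OLSFit, fit_ols_loglog

__all__ = ["intraspecific_fit", "ResamplingCurve", "adequacy_curve", "table2_frame"]


def intraspecific_fit(data: pd.DataFrame, species: str, sex: str) -> OLSFit:
    """OLS of ln(dry weight) on ln(ITD) within one species and sex.

    Requires at least 4 specimens with both measurements (fewer would
    leave <= 1 residual degree of freedom beyond the slope test's
    minimum) and non-constant ITD.
    """
    sub = data[(data["species"].astype(str) == species)
               & (data["sex"].astype(str) == sex)]
    sub = sub.dropna(subset=["itd_mm", "dry_weight_mg"])
    if len(sub) < 4:
        raise ValueError(
            f"{species} ({sex}): need >= 4 specimens with ITD and dry weight, "
            f"got {len(sub)}"
        )
    x = sub["itd_mm"].to_numpy(dtype=float)
    if np.ptp(np.log(x)) == 0:
        raise ValueError(f"{species} ({sex}): all ITD values equal; slope undefined")
    return fit_ols_loglog(x, sub["dry_weight_mg"].to_numpy(dtype=float))


def table2_frame(data: pd.DataFrame, targets: list[tuple[str, str]]) -> pd.DataFrame:
    """Per-species fit table: one row per (species, sex) target.

    Columns follow the conventional intraspecific reporting layout:
    region, group, species, sex, F (df1, df2), alpha +/- SE,
    beta +/- SE, adjusted R^2, p, n.
    """
    rows = []
    for species, sex in targets:
        fit = intraspecific_fit(data, species, sex)
        sub = data[data["species"].astype(str) == species]
        rows.append({
            "region": sub["region"].mode().iat[0] if "region" in sub else "",
            "group": sub["group"].mode().iat[0] if "group" in sub else "",
            "species": species,
            "sex": sex,
            "f_stat": fit.f_stat,
            "df1": fit.df1,
            "df2": fit.df2,
            "alpha": fit.alpha,
            "alpha_se": fit.alpha_se,
            "beta": fit.beta,
            "beta_se": fit.beta_se,
            "adj_r2": fit.adj_r2,
            "p_value": fit.p_value,
            "n": fit.n,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ResamplingCurve:
    """Subsample-mean trajectory against the full-sample confidence band.

    For each subsample size n, ``replicates`` random subsamples (without
    replacement) yield a distribution of subsample means:
    ``mean_per_n`` is its average and ``envelope_lo``/``envelope_hi``
    its 2.5%/97.5% quantiles.  ``band`` is the full-sample mean's
    t-based 95% CI.  ``adequate_n`` is the smallest n from which the
    *envelope* -- the spread of subsample means, not just their average,
    which converges trivially -- stays inside the band for every larger
    n; this is the size at which sampling variance has stabilized
    within the full-sample confidence interval.
    """

    n_grid: tuple[int, ...]
    mean_per_n: tuple[float, ...]
    envelope_lo: tuple[float, ...]
    envelope_hi: tuple[float, ...]
    band: tuple[float, float]
    full_mean: float
    adequate_n: int
    seed: int
    replicates: int

    def to_frame(self) -> pd.DataFrame:
        lo, hi = self.band
        return pd.DataFrame({
            "n": self.n_grid,
            "mean": self.mean_per_n,
            "envelope_lo": self.envelope_lo,
            "envelope_hi": self.envelope_hi,
            "band_lo": lo,
            "band_hi": hi,
        })


def adequacy_curve(values, replicates: int = 100, seed: int = 0) -> ResamplingCurve:
    """Resampling-based adequate sample size for a trait mean.

    For each n in 1..N, ``replicates`` random n-subsamples (without
    replacement) are drawn and their means summarized; the adequate
    sample size is the smallest n whose 95% envelope of subsample means
    -- and every later one's -- lies inside the 95% t-interval of the
    full-sample mean.  At n = N the subsample is the sample, so the
    curve and envelope end exactly at the full-sample mean and
    ``adequate_n`` always exists.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 3:
        raise ValueError(f"need >= 3 values, got {v.shape}")
    n_total = len(v)
    full_mean = float(v.mean())
    sem = float(v.std(ddof=1) / np.sqrt(n_total))
    t = float(stats.t.ppf(0.975, n_total - 1))
    band = (full_mean - t * sem, full_mean + t * sem)

    rng = np.random.default_rng(seed)
    means = np.empty(n_total)
    env_lo = np.empty(n_total)
    env_hi = np.empty(n_total)
    for i, n in enumerate(range(1, n_total + 1)):
        if n == n_total:
            means[i] = env_lo[i] = env_hi[i] = full_mean  # subsample == sample
            continue
        reps = np.array([
            v[rng.choice(n_total, size=n, replace=False)].mean()
            for _ in range(replicates)
        ])
        means[i] = reps.mean()
        env_lo[i] = np.quantile(reps, 0.025)
        env_hi[i] = np.quantile(reps, 0.975)

    tol = 1e-12 * max(1.0, abs(full_mean))  # zero-variance data: band has zero width
    inside = (env_lo >= band[0] - tol) & (env_hi <= band[1] + tol)
    adequate = n_total
    for i in range(n_total - 1, -1, -1):
        if not inside[i]:
            break
        adequate = i + 1
    return ResamplingCurve(
        n_grid=tuple(range(1, n_total + 1)),
        mean_per_n=tuple(float(m) for m in means),
        envelope_lo=tuple(float(m) for m in env_lo),
        envelope_hi=tuple(float(m) for m in env_hi),
        band=band,
        full_mean=full_mean,
        adequate_n=int(adequate),
        seed=seed,
        replicates=replicates,
    )
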