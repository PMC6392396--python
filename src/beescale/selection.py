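"""Model evaluation and ranking.

Three complementary scores, reported together in a selection table:

* Bayesian R^2 -- per posterior draw, Var(linear predictor) /
  (Var(linear predictor) + residual variance), summarized over draws;
* grouped K-fold cross-validation -- folds partition *species*, so every
  held-out specimen belongs to a species the training run never saw;
  the score is -2 x the summed held-out log predictive density
  (deviance scale, lower is better), with held-out species' random
  effects integrated analytically over their population (or Brownian
  conditional) distribution;
* RMSE on the mg scale, from posterior-median predictions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .glmm import (
    FittedGLMM,
    MCMCSettings,
    ModelSpec,
    _PhyloConditional,
    _fixed_design,
    fit_interspecific,
    fit_interspecific_phylo,
)
from .trees import Phylogeny
from .util import spawn_seed

__all__ = [
    "CVResult",
    "ComparisonRow",
    "bayes_r2",
    "grouped_kfold_split",
    "kfold_cv",
    "rmse",
    "compare_models",
    "comparison_to_frame",
    "comparison_to_markdown",
]


def bayes_r2(model: FittedGLMM, data: pd.DataFrame) -> dict:
    """Posterior distribution of Bayesian R^2 on the training data.

    Per draw: Var_n(eta) / (Var_n(eta) + sigma^2), where eta is the full
    linear predictor (fixed effects plus fitted random intercepts).
    Returns mean, 5%/95% quantiles, and the per-draw values.
    """
    rng = np.random.default_rng(0)  # unused when all groups were seen in training
    eta = model.linear_predictor_draws(data, rng=rng)
    fit_var = eta.var(axis=0)
    if np.max(fit_var) <= 1e-12:
        raise ValueError("zero-variance fitted values: R^2 undefined "
                         "(intercept-only model?)")
    sigma2 = model.sigma_draws() ** 2
    r2 = fit_var / (fit_var + sigma2)
    return {
        "mean": float(r2.mean()),
        "q05": float(np.quantile(r2, 0.05)),
        "q95": float(np.quantile(r2, 0.95)),
        "draws": r2,
    }


def grouped_kfold_split(
    data: pd.DataFrame,
    k: int = 10,
    group_key: str = "species",
    seed: int = 0,
) -> dict[str, int]:
    """Deal the distinct groups into k folds of near-equal group counts.

    Depends only on the set of group labels and the seed (not on record
    order), so the same table shuffled gives the same assignment.  All
    specimens of one group share a fold; fold sizes differ by at most 1.
    """
    groups = sorted(data[group_key].astype(str).unique())
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(groups):
        raise ValueError(f"k={k} exceeds the {len(groups)} distinct groups")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(groups))
    return {groups[g]: int(i % k) for i, g in enumerate(order)}


@dataclass(frozen=True)
class CVResult:
    """Grouped K-fold score: -2 x held-out log predictive density."""

    k: int
    fold_scores: tuple[float, ...]
    total_score: float
    seed: int
    fold_assignment: dict[str, int]
    unreliable: bool = False  # any fold's refit failed convergence


def _held_out_lpd(fit: FittedGLMM, test: pd.DataFrame, lny: np.ndarray) -> float:
    """Summed log predictive density of held-out specimens.

    Held-out species' intercepts are integrated analytically: they add
    sigma_species^2 (times the Brownian conditional variance factor for
    phylogenetic fits, whose conditional mean given the training
    species' sampled effects is also used) to the per-draw predictive
    variance.  An unseen region likewise adds sigma_region^2.
    """
    X, _, _ = _fixed_design(test, fit.spec, fit.levels)
    B = fit.beta_draws().to_numpy()
    eta = X @ B.T                                  # (n, n_draws)
    nd = fit.n_draws
    sigma2 = fit.sigma_draws() ** 2
    var = np.tile(sigma2, (len(test), 1))

    if fit.spec.nested_random:
        sig_r2 = fit.draws["sigma_region"].to_numpy() ** 2
        sig_s2 = fit.draws["sigma_species"].to_numpy() ** 2
        region_cols = {r: f"re_region[{r}]" for r in fit.levels.region}
        unit_cols = {u: f"re_species[{u[0]}|{u[1]}]" for u in fit.levels.units}
        cond = None
        if fit.spec.phylo and fit.species_corr is not None:
            unit_mat = fit.draws[[unit_cols[u] for u in fit.levels.units]].to_numpy()
            cond = _PhyloConditional(fit.species_corr, fit.levels.units)
        for i, row in enumerate(test.itertuples(index=False)):
            region = str(getattr(row, "region"))
            species = str(getattr(row, "species"))
            if region in region_cols:
                eta[i] += fit.draws[region_cols[region]].to_numpy()
            else:
                var[i] += sig_r2
            unit = (region, species)
            if unit in unit_cols:
                eta[i] += fit.draws[unit_cols[unit]].to_numpy()
            elif cond is not None and species in cond.tips:
                mean, relvar = cond.conditional(species, unit_mat)
                eta[i] += mean
                var[i] += sig_s2 * relvar
            else:
                var[i] += sig_s2

    logdens = (
        -0.5 * np.log(2 * math.pi * var)
        - 0.5 * (lny[:, None] - eta) ** 2 / var
    )
    lpd = logsumexp(logdens, axis=1) - math.log(nd)
    return float(lpd.sum())


def kfold_cv(
    spec: ModelSpec | str,
    data: pd.DataFrame,
    folds: dict[str, int],
    settings: MCMCSettings | None = None,
    tree: Phylogeny | None = None,
    priors: dict | None = None,
) -> CVResult:
    """Refit on k-1 folds, score the held-out fold, sum over folds.

    Each fold's refit gets a seed derived from the base seed and the
    fold index; a refit flagged as non-converged marks the whole result
    unreliable (it is still reported).
    """
    from .glmm import MODEL_LABELS

    if isinstance(spec, str):
        spec = MODEL_LABELS[spec]
    settings = settings or MCMCSettings()
    ks = sorted(set(folds.values()))
    if len(ks) < 2:
        raise ValueError("need at least 2 folds")
    species = data["species"].astype(str)
    unassigned = sorted(set(species.unique()) - set(folds))
    if unassigned:
        raise ValueError(f"species without a fold: {unassigned}")

    fold_scores = []
    unreliable = False
    for f in ks:
        in_fold = species.map(folds).to_numpy() == f
        train, test = data.loc[~in_fold], data.loc[in_fold]
        fold_settings = MCMCSettings(
            iterations=settings.iterations, burn_in=settings.burn_in,
            chains=settings.chains, seed=spawn_seed(settings.seed, "fold", f),
            walkers_per_chain=settings.walkers_per_chain,
            max_stored_draws=settings.max_stored_draws,
        )
        import warnings as _warnings

        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always")
            if spec.phylo:
                fit = fit_interspecific_phylo(train, spec, tree, fold_settings, priors)
            else:
                fit = fit_interspecific(train, spec, fold_settings, priors)
        if not fit.converged:
            unreliable = True
        lny = np.log(test[spec.response].to_numpy(dtype=float))
        lpd = _held_out_lpd(fit, test, lny)
        fold_scores.append(-2.0 * lpd)

    return CVResult(
        k=len(ks),
        fold_scores=tuple(fold_scores),
        total_score=float(sum(fold_scores)),
        seed=settings.seed,
        fold_assignment=dict(folds),
        unreliable=unreliable,
    )


def rmse(observed, predicted) -> float:
    """Root-mean-square error on the response (mg) scale."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.ndim != 1:
        raise ValueError("observed and predicted must be 1-D and equal length")
    if len(o) == 0:
        raise ValueError("need at least one pair")
    return float(np.sqrt(np.mean((o - p) ** 2)))


@dataclass(frozen=True)
class ComparisonRow:
    """One line of the selection table; ranking key is kcv ascending."""

    label: str
    bayes_r2: float
    kcv: float
    delta_kcv: float
    rmse_mg: float
    unreliable: bool = False


def compare_models(
    fits: list[FittedGLMM],
    data: pd.DataFrame,
    folds: dict[str, int],
    tree: Phylogeny | None = None,
) -> list[ComparisonRow]:
    """Score each fitted model on the shared data and rank by K-CV.

    All fits must carry the same training-data fingerprint (mixed
    fingerprints indicate the models were not fitted to this table).
    ``tree`` is needed to refit any phylogenetic specs during CV.
    """
    fps = {f.data_fingerprint for f in fits}
    if len(fps) > 1:
        raise ValueError("fits carry different data fingerprints; refusing to compare")

    rows = []
    observed = data[fits[0].spec.response].to_numpy(dtype=float)
    for fit in fits:
        r2 = bayes_r2(fit, data)["mean"]
        cv = kfold_cv(fit.spec, data, folds, fit.settings, tree=tree,
                      priors=fit.priors)
        point = np.array([p.point for p in fit.predict(data)])
        rows.append((fit.spec.label(), r2, cv.total_score,
                     rmse(observed, point), cv.unreliable))
    best = min(r[2] for r in rows)
    out = [
        ComparisonRow(label=l, bayes_r2=r2, kcv=cv, delta_kcv=cv - best,
                      rmse_mg=e, unreliable=u)
        for l, r2, cv, e, u in rows
    ]
    out.sort(key=lambda r: r.kcv)
    return out


def comparison_to_frame(rows: list[ComparisonRow]) -> pd.DataFrame:
    return pd.DataFrame({
        "model": [r.label for r in rows],
        "bayes_r2": [r.bayes_r2 for r in rows],
        "kcv": [r.kcv for r in rows],
        "delta_kcv": [r.delta_kcv for r in rows],
        "rmse_mg": [r.rmse_mg for r in rows],
        "unreliable": [r.unreliable for r in rows],
    })


def comparison_to_markdown(rows: list[ComparisonRow]) -> str:
    lines = ["| Model | R² | K-CV | Δ | RMSE (mg) |",
             "|---|---|---|---|---|"]
    for r in rows:
        flag = " *" if r.unreliable else ""
        lines.append(
            f"| {r.label}{flag} | {r.bayes_r2:.3f} | {r.kcv:.1f} "
            f"| {r.delta_kcv:.1f} | {r.rmse_mg:.3f} |"
        )
    return "\n".join(lines) + "\n"
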