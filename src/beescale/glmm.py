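"""Hierarchical Bayesian ln-ln allometric models.

The interspecific body-size model is a lognormal power law with
taxonomic and biogeographic structure:

    ln(dry weight) = ln(alpha) + beta * ln(ITD)
                     [+ group and sex offsets and slope interactions]
                     + region intercept + species-within-region intercept
                     + residual,

with Normal random intercepts for region and for species nested in
region, and a Normal residual on the ln scale.  The phylogenetic
variant replaces the i.i.d. species intercepts with a multivariate
Normal whose correlation is the (normalized) shared-path-length matrix
of a chronogram -- Brownian-motion covariance at and above the genus
level.

Inference
---------
Because the likelihood and all priors on coefficients are Gaussian, the
fixed effects and every random intercept can be integrated out
analytically.  The marginal likelihood of the observations then depends
only on the two or three standard deviations (region SD, species SD,
residual SD), which are sampled with an affine-invariant ensemble
sampler (emcee).  Coefficient and random-intercept draws are
reconstituted exactly from their Gaussian conditional distribution
given each sampled SD vector, so the resulting joint draws are exact
posterior samples -- no approximation beyond Monte Carlo error.  This
low-dimensional marginalized sampler is fast and has no divergent
transitions by construction; convergence is still checked with split-R̂
on every reported parameter.

Priors are weakly informative and overridable: Normal(0, 5) on the
ln-scale intercept, Normal(0, 2) on slopes and offsets, half-Normal(0, 1)
on all SDs.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field as dc_field, replace, asdict
from pathlib import Path
from typing import Mapping, Sequence

import emcee
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .prediction import PredictionResult, predict_from_equation
from .registry import AllometricEquation
from .trees import Phylogeny, phylo_covariance
from .util import data_fingerprint, spawn_seed, split_rhat

__all__ = [
    "FIXED_TERMS",
    "MODEL_LABELS",
    "ModelSpec",
    "MCMCSettings",
    "DEFAULT_PRIORS",
    "FittedGLMM",
    "AllometricGLMM",
    "SingularDesignError",
    "NonConvergenceWarning",
    "fit_interspecific",
    "fit_interspecific_phylo",
    "predict_dry_weight",
    "predictions_frame",
]

FIXED_TERMS = ("group", "sex", "group_slope", "sex_slope")


class SingularDesignError(ValueError):
    """The fixed-effect design matrix is rank deficient for this data."""


class NonConvergenceWarning(UserWarning):
    """A fit whose split-R̂ exceeded the acceptance threshold."""


@dataclass(frozen=True)
class ModelSpec:
    """What goes into the linear predictor.

    ``fixed_terms`` is a subset of :data:`FIXED_TERMS`; slope
    interactions require their main effect.  ``nested_random`` adds the
    (1 | region/species) intercepts; ``phylo`` constrains the species
    term by a phylogeny (supplied at fit time).
    """

    response: str = "dry_weight_mg"
    predictor: str = "itd_mm"
    fixed_terms: tuple[str, ...] = ()
    nested_random: bool = True
    phylo: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.fixed_terms) - set(FIXED_TERMS)
        if unknown:
            raise ValueError(f"unknown fixed terms {sorted(unknown)}")
        if "group_slope" in self.fixed_terms and "group" not in self.fixed_terms:
            raise ValueError("group_slope interaction requires the group main effect")
        if "sex_slope" in self.fixed_terms and "sex" not in self.fixed_terms:
            raise ValueError("sex_slope interaction requires the sex main effect")
        if self.phylo and not self.nested_random:
            raise ValueError("phylo constraint applies to the nested species term")

    def label(self) -> str:
        parts = ["ln(w) ~ ln(x)"]
        if "group" in self.fixed_terms:
            parts.append("group")
        if "sex" in self.fixed_terms:
            parts.append("sex")
        if "group_slope" in self.fixed_terms:
            parts.append("group:ln(x)")
        if "sex_slope" in self.fixed_terms:
            parts.append("sex:ln(x)")
        s = " + ".join(parts)
        if self.nested_random:
            s += " + (1|region/species)"
        if self.phylo:
            s += " [phylo]"
        return s


#: Named model specs mirroring the published model-selection ladder.
MODEL_LABELS: dict[str, ModelSpec] = {
    "itd": ModelSpec(fixed_terms=(), nested_random=False),
    "itd-re": ModelSpec(fixed_terms=()),
    "sex": ModelSpec(fixed_terms=("sex",), nested_random=False),
    "sex-itd": ModelSpec(fixed_terms=("sex", "sex_slope"), nested_random=False),
    "taxo": ModelSpec(fixed_terms=("group",)),
    "taxo-sex": ModelSpec(fixed_terms=("group", "sex")),
    "taxo-sex-itd": ModelSpec(fixed_terms=("group", "sex", "sex_slope")),
    "taxo-full": ModelSpec(fixed_terms=("group", "sex", "group_slope", "sex_slope")),
    "phylo": ModelSpec(fixed_terms=(), phylo=True),
    "phylo-sex": ModelSpec(fixed_terms=("sex",), phylo=True),
    "phylo-sex-itd": ModelSpec(fixed_terms=("sex", "sex_slope"), phylo=True),
}


@dataclass(frozen=True)
class MCMCSettings:
    """Sampler settings.

    ``iterations`` is the total chain length, of which the first
    ``burn_in`` steps are discarded (the published default split is
    2000/1000).  ``adapt_delta`` and ``max_tree_depth`` are accepted for
    interface compatibility with gradient-based (NUTS) samplers and are
    ignored by the ensemble sampler used here.
    """

    iterations: int = 2000
    burn_in: int = 1000
    chains: int = 4
    adapt_delta: float = 0.99
    max_tree_depth: int = 10
    seed: int = 1
    walkers_per_chain: int = 4
    max_stored_draws: int = 1000

    def __post_init__(self) -> None:
        if not (0 < self.burn_in < self.iterations):
            raise ValueError("require 0 < burn_in < iterations")
        if not (0 < self.adapt_delta < 1):
            raise ValueError("adapt_delta must be in (0, 1)")
        if self.chains < 1 or self.walkers_per_chain < 1:
            raise ValueError("chains and walkers_per_chain must be >= 1")


DEFAULT_PRIORS: dict[str, float] = {
    "intercept_sd": 5.0,   # Normal(0, 5) on the ln-scale intercept
    "coef_sd": 2.0,        # Normal(0, 2) on slopes and offsets
    "sd_scale": 1.0,       # half-Normal(0, 1) on all random/residual SDs
}

RHAT_THRESHOLD = 1.05


# ---------------------------------------------------------------------------
# design matrices


@dataclass
class _Levels:
    group: list[str]
    sex: list[str]
    region: list[str]
    units: list[tuple[str, str]]  # (region, species)


def _fixed_design(df: pd.DataFrame, spec: ModelSpec,
                  levels: _Levels | None) -> tuple[np.ndarray, list[str], _Levels]:
    """Build the fixed-effect design matrix (treatment coding).

    With ``levels`` given (prediction time) the stored factor levels are
    used and unseen group/sex labels raise; otherwise levels are taken
    from the data (sorted, first level = baseline).
    """
    x = df[spec.predictor].to_numpy(dtype=float)
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise ValueError(f"{spec.predictor} must be positive and finite")
    lnx = np.log(x)

    if levels is None:
        levels = _Levels(
            group=sorted(df["group"].astype(str).unique()) if "group" in spec.fixed_terms else [],
            sex=sorted(df["sex"].astype(str).unique()) if "sex" in spec.fixed_terms else [],
            region=[],
            units=[],
        )
    cols: list[np.ndarray] = [np.ones(len(df)), lnx]
    names = ["Intercept", "ln_x"]

    def dummies(var: str, lev: list[str]) -> list[tuple[str, np.ndarray]]:
        vals = df[var].astype(str).to_numpy()
        unseen = sorted(set(vals) - set(lev))
        if unseen:
            raise ValueError(f"unseen {var} level(s) {unseen}; model knows {lev}")
        return [(f"{var}={l}", (vals == l).astype(float)) for l in lev[1:]]

    if "group" in spec.fixed_terms:
        if len(levels.group) < 2:
            raise SingularDesignError(
                f"group term requested but only {len(levels.group)} group level(s) present"
            )
        for name, col in dummies("group", levels.group):
            names.append(name)
            cols.append(col)
    if "sex" in spec.fixed_terms:
        if len(levels.sex) < 2:
            raise SingularDesignError(
                f"sex term requested but only {len(levels.sex)} sex level(s) present"
            )
        for name, col in dummies("sex", levels.sex):
            names.append(name)
            cols.append(col)
    if "group_slope" in spec.fixed_terms:
        for name, col in dummies("group", levels.group):
            names.append(f"{name}:ln_x")
            cols.append(col * lnx)
    if "sex_slope" in spec.fixed_terms:
        for name, col in dummies("sex", levels.sex):
            names.append(f"{name}:ln_x")
            cols.append(col * lnx)

    X = np.column_stack(cols)
    return X, names, levels


def _indicator(values: Sequence, levels: Sequence) -> np.ndarray:
    pos = {l: k for k, l in enumerate(levels)}
    Z = np.zeros((len(values), len(levels)))
    for i, v in enumerate(values):
        Z[i, pos[v]] = 1.0
    return Z


# ---------------------------------------------------------------------------
# fitted model container


@dataclass
class FittedGLMM:
    """Posterior draws plus everything needed to predict and audit.

    ``draws`` holds one row per retained joint posterior draw: the SDs,
    every fixed coefficient (``beta[...]`` columns), every region
    intercept (``re_region[...]``) and every species-within-region
    intercept (``re_species[region|species]``), with a ``chain`` column
    recording the originating sampler chain.  ``rhat`` maps each of
    those parameters to its split-R̂.
    """

    spec: ModelSpec
    settings: MCMCSettings
    priors: dict[str, float]
    draws: pd.DataFrame
    rhat: dict[str, float]
    diagnostics: dict
    x_cols: list[str]
    levels: _Levels
    species_corr: pd.DataFrame | None
    data_fingerprint: str

    # -- convenience accessors -------------------------------------------

    @property
    def n_draws(self) -> int:
        return len(self.draws)

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", False))

    def beta_draws(self) -> pd.DataFrame:
        return self.draws[[c for c in self.draws.columns if c.startswith("beta[")]]

    def sigma_draws(self) -> np.ndarray:
        return self.draws["sigma"].to_numpy()

    # -- prediction -------------------------------------------------------

    def linear_predictor_draws(
        self,
        newdata: pd.DataFrame,
        rng: np.random.Generator | None = None,
        include_residual: bool = False,
    ) -> np.ndarray:
        """(n_records, n_draws) draws of the ln-scale predictor.

        Seen regions/species use their sampled intercepts.  An unseen
        species is integrated over the species population distribution
        (or, for phylogenetic models, over its Brownian conditional
        given the sampled effects of the training species when it is a
        tip of the tree); an unseen region is integrated over the region
        distribution, with a warning.
        """
        rng = rng or np.random.default_rng(spawn_seed(self.settings.seed, "predict"))
        X, _, _ = _fixed_design(newdata, self.spec, self.levels)
        B = self.beta_draws().to_numpy()  # (n_draws, p)
        eta = X @ B.T  # (n, n_draws)
        nd = self.n_draws

        if self.spec.nested_random:
            sig_r = self.draws["sigma_region"].to_numpy()
            sig_s = self.draws["sigma_species"].to_numpy()
            region_cols = {r: f"re_region[{r}]" for r in self.levels.region}
            unit_cols = {u: f"re_species[{u[0]}|{u[1]}]" for u in self.levels.units}
            unit_mat = self.draws[[unit_cols[u] for u in self.levels.units]].to_numpy()

            cond = None
            if self.spec.phylo and self.species_corr is not None:
                cond = _PhyloConditional(self.species_corr, self.levels.units)

            unseen_regions = set()
            for i, row in enumerate(newdata.itertuples(index=False)):
                region = str(getattr(row, "region"))
                species = str(getattr(row, "species"))
                if region in region_cols:
                    eta[i] += self.draws[region_cols[region]].to_numpy()
                else:
                    unseen_regions.add(region)
                    eta[i] += rng.standard_normal(nd) * sig_r
                unit = (region, species)
                if unit in unit_cols:
                    eta[i] += self.draws[unit_cols[unit]].to_numpy()
                elif cond is not None and species in cond.tips:
                    mean, relvar = cond.conditional(species, unit_mat)
                    eta[i] += mean + rng.standard_normal(nd) * sig_s * math.sqrt(relvar)
                else:
                    eta[i] += rng.standard_normal(nd) * sig_s
            if unseen_regions:
                warnings.warn(
                    f"region(s) {sorted(unseen_regions)} unseen in training; "
                    "integrated over the region random-effect distribution",
                    UserWarning,
                    stacklevel=2,
                )
        if include_residual:
            eta = eta + rng.standard_normal(eta.shape) * self.sigma_draws()
        return eta

    def predict(self, newdata: pd.DataFrame, level: float = 0.90,
                rng: np.random.Generator | None = None,
                include_residual: bool = False) -> list[PredictionResult]:
        eta = self.linear_predictor_draws(newdata, rng=rng,
                                          include_residual=include_residual)
        mg = np.exp(eta)
        lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
        out = []
        for row in mg:
            out.append(PredictionResult(
                point=float(np.median(row)),
                se=float(np.std(row)),
                ci_low=float(np.quantile(row, lo_q)),
                ci_high=float(np.quantile(row, hi_q)),
                scale_note="posterior median of exponentiated draws",
                level=level,
            ))
        return out

    # -- persistence ------------------------------------------------------

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.draws.to_csv(path / "draws.csv", index=False)
        meta = {
            "spec": asdict(self.spec),
            "settings": asdict(self.settings),
            "priors": self.priors,
            "rhat": self.rhat,
            "diagnostics": self.diagnostics,
            "x_cols": self.x_cols,
            "levels": {
                "group": self.levels.group,
                "sex": self.levels.sex,
                "region": self.levels.region,
                "units": [list(u) for u in self.levels.units],
            },
            "data_fingerprint": self.data_fingerprint,
        }
        (path / "meta.json").write_text(json.dumps(meta, indent=2), encoding="utf-8")
        if self.species_corr is not None:
            self.species_corr.to_csv(path / "species_corr.csv")

    @classmethod
    def from_dir(cls, path: str | Path) -> "FittedGLMM":
        path = Path(path)
        meta = json.loads((path / "meta.json").read_text(encoding="utf-8"))
        spec = ModelSpec(**{**meta["spec"], "fixed_terms": tuple(meta["spec"]["fixed_terms"])})
        corr_path = path / "species_corr.csv"
        return cls(
            spec=spec,
            settings=MCMCSettings(**meta["settings"]),
            priors=meta["priors"],
            draws=pd.read_csv(path / "draws.csv"),
            rhat=meta["rhat"],
            diagnostics=meta["diagnostics"],
            x_cols=meta["x_cols"],
            levels=_Levels(
                group=meta["levels"]["group"],
                sex=meta["levels"]["sex"],
                region=meta["levels"]["region"],
                units=[tuple(u) for u in meta["levels"]["units"]],
            ),
            species_corr=pd.read_csv(corr_path, index_col=0) if corr_path.exists() else None,
            data_fingerprint=meta["data_fingerprint"],
        )


class _PhyloConditional:
    """Brownian conditional of a new species' effect given training units."""

    def __init__(self, corr: pd.DataFrame, units: list[tuple[str, str]]):
        self.tips = set(corr.index)
        self.unit_species = [sp for _, sp in units]
        C = corr.loc[self.unit_species, self.unit_species].to_numpy()
        self.Cinv = np.linalg.inv(C + 1e-8 * np.eye(len(C)))
        self.corr = corr

    def conditional(self, species: str, unit_mat: np.ndarray) -> tuple[np.ndarray, float]:
        c = self.corr.loc[species, self.unit_species].to_numpy(dtype=float)
        w = self.Cinv @ c
        mean = unit_mat @ w               # per-draw conditional mean
        relvar = float(max(1.0 - c @ w, 0.0))
        return mean, relvar


# ---------------------------------------------------------------------------
# the estimator


class AllometricGLMM(RegressorMixin, BaseEstimator):
    """Bayesian hierarchical ln-ln allometry, scikit-learn style.

    Parameters
    ----------
    fixed_terms : tuple of str
        Subset of ``("group", "sex", "group_slope", "sex_slope")``.
    nested_random : bool
        Include (1 | region/species) random intercepts.
    tree : Phylogeny or None
        Chronogram constraining the species term (phylogenetic model).
    priors : dict or None
        Overrides for :data:`DEFAULT_PRIORS`.
    iterations, burn_in, chains, walkers_per_chain, seed, max_stored_draws
        Sampler settings (see :class:`MCMCSettings`).
    check_convergence : bool
        Warn (NonConvergenceWarning) when any split-R̂ exceeds 1.05.

    After ``fit``, the exact posterior draws and diagnostics live in
    ``result_`` (a :class:`FittedGLMM`); ``rhat_``, ``converged_`` and
    ``draws_`` mirror its fields.
    """

    def __init__(
        self,
        fixed_terms: tuple[str, ...] = (),
        nested_random: bool = True,
        tree: Phylogeny | None = None,
        priors: dict | None = None,
        iterations: int = 2000,
        burn_in: int = 1000,
        chains: int = 4,
        walkers_per_chain: int = 4,
        seed: int = 1,
        max_stored_draws: int = 1000,
        response: str = "dry_weight_mg",
        predictor: str = "itd_mm",
        check_convergence: bool = True,
    ):
        self.fixed_terms = fixed_terms
        self.nested_random = nested_random
        self.tree = tree
        self.priors = priors
        self.iterations = iterations
        self.burn_in = burn_in
        self.chains = chains
        self.walkers_per_chain = walkers_per_chain
        self.seed = seed
        self.max_stored_draws = max_stored_draws
        self.response = response
        self.predictor = predictor
        self.check_convergence = check_convergence

    # -- fitting ----------------------------------------------------------

    def fit(self, X: pd.DataFrame, y=None) -> "AllometricGLMM":
        df = X.copy()
        spec = ModelSpec(
            response=self.response,
            predictor=self.predictor,
            fixed_terms=tuple(self.fixed_terms),
            nested_random=self.nested_random,
            phylo=self.tree is not None,
        )
        settings = MCMCSettings(
            iterations=self.iterations, burn_in=self.burn_in, chains=self.chains,
            seed=self.seed, walkers_per_chain=self.walkers_per_chain,
            max_stored_draws=self.max_stored_draws,
        )
        priors = {**DEFAULT_PRIORS, **(self.priors or {})}
        self.result_ = _fit_glmm(df, y, spec, settings, priors, self.tree,
                                 check_convergence=self.check_convergence)
        self.draws_ = self.result_.draws
        self.rhat_ = self.result_.rhat
        self.converged_ = self.result_.converged
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Posterior-median dry weight (mg) per record."""
        return np.array([p.point for p in self.result_.predict(X)])

    def predict_interval(self, X: pd.DataFrame, level: float = 0.90) -> pd.DataFrame:
        return predictions_frame(self.result_.predict(X, level=level))


def _fit_glmm(
    df: pd.DataFrame,
    y,
    spec: ModelSpec,
    settings: MCMCSettings,
    priors: Mapping[str, float],
    tree: Phylogeny | None,
    check_convergence: bool = True,
) -> FittedGLMM:
    # -- response ---------------------------------------------------------
    if y is None:
        if spec.response not in df.columns:
            raise ValueError(f"response column {spec.response!r} missing")
        y = df[spec.response]
    yv = np.asarray(y, dtype=float)
    mask = np.isfinite(yv)
    if not mask.all():
        raise ValueError(f"{(~mask).sum()} record(s) lack the response {spec.response!r}")
    if np.any(yv <= 0):
        raise ValueError("response must be positive (lognormal model)")
    lny = np.log(yv)

    needed = {"species", "region", spec.predictor}
    if "group" in spec.fixed_terms or "group_slope" in spec.fixed_terms:
        needed.add("group")
    if "sex" in spec.fixed_terms or "sex_slope" in spec.fixed_terms:
        needed.add("sex")
    missing_cols = needed - set(df.columns)
    if missing_cols:
        raise ValueError(f"missing column(s) {sorted(missing_cols)}")
    if df["species"].nunique() < 2:
        raise ValueError("need >= 2 species")

    X, x_cols, levels = _fixed_design(df, spec, None)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError(
            "fixed-effect design is rank deficient; check that every requested "
            f"factor varies in the data (columns: {x_cols})"
        )

    # -- random-effect structure -----------------------------------------
    blocks = [X]
    d_fix = np.array(
        [priors["intercept_sd"] ** 2]
        + [priors["coef_sd"] ** 2] * (X.shape[1] - 1)
    )
    region_levels: list[str] = []
    unit_levels: list[tuple[str, str]] = []
    corr_all: pd.DataFrame | None = None
    n_r = n_s = 0
    if spec.nested_random:
        region_levels = sorted(df["region"].astype(str).unique())
        units = list(zip(df["region"].astype(str), df["species"].astype(str)))
        unit_levels = sorted(set(units))
        Zr = _indicator(df["region"].astype(str).to_numpy(), region_levels)
        Zs = _indicator(units, unit_levels)
        n_r, n_s = len(region_levels), len(unit_levels)
        if spec.phylo:
            if tree is None:
                raise ValueError("phylo spec requires a tree")
            tips = set(tree.tip_labels)
            absent = sorted({sp for _, sp in unit_levels} - tips)
            if absent:
                raise ValueError(f"species missing from tree: {absent}")
            cov = phylo_covariance(tree)
            dd = np.sqrt(np.diag(cov.to_numpy()))
            corr_all = pd.DataFrame(
                cov.to_numpy() / np.outer(dd, dd), index=cov.index, columns=cov.columns
            )
            sp_units = [sp for _, sp in unit_levels]
            C_units = corr_all.loc[sp_units, sp_units].to_numpy()
            Ls = np.linalg.cholesky(C_units + 1e-10 * np.eye(n_s))
            blocks += [Zr, Zs @ Ls]
        else:
            Ls = np.eye(n_s)
            blocks += [Zr, Zs]
    W = np.column_stack(blocks)
    n, m = W.shape
    p = X.shape[1]

    WtW = W.T @ W
    Wty = W.T @ lny
    yty = float(lny @ lny)

    sd_names = ["sigma"] + (["sigma_region", "sigma_species"] if spec.nested_random else [])
    k = len(sd_names)
    sd_scale = priors["sd_scale"]

    def log_post(theta: np.ndarray) -> float:
        if np.any(np.abs(theta) > 12):
            return -np.inf
        sds = np.exp(theta)
        sigma2 = sds[0] ** 2
        d = d_fix.copy()
        if spec.nested_random:
            d = np.concatenate([d, np.full(n_r, sds[1] ** 2), np.full(n_s, sds[2] ** 2)])
        sd_d = np.sqrt(d)
        M = np.eye(m) + (sd_d[:, None] * WtW * sd_d[None, :]) / sigma2
        try:
            L = np.linalg.cholesky(M)
        except np.linalg.LinAlgError:
            return -np.inf
        a = sd_d * Wty
        z = np.linalg.solve(L, a)
        quad = (yty - (z @ z) / sigma2) / sigma2
        logdet = n * math.log(sigma2) + 2.0 * float(np.sum(np.log(np.diag(L))))
        ll = -0.5 * (n * math.log(2 * math.pi) + logdet + quad)
        # half-Normal(0, sd_scale) on each SD plus log-Jacobian of exp
        lp = float(np.sum(-0.5 * (sds / sd_scale) ** 2 + theta))
        return ll + lp

    # -- ensemble sampling over the SD parameters -------------------------
    nwalkers = max(settings.chains * settings.walkers_per_chain, 2 * k + 2)
    if nwalkers % 2:
        nwalkers += 1
    rng = np.random.default_rng(spawn_seed(settings.seed, "mcmc"))
    sd_y = float(np.std(lny)) or 0.5
    centre = math.log(max(sd_y / 2, 1e-3))
    p0 = centre + 0.5 * rng.standard_normal((nwalkers, k))

    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(nwalkers, k, log_post, moves=moves)
    sampler.random_state = np.random.RandomState(
        spawn_seed(settings.seed, "emcee")
    ).get_state()
    sampler.run_mcmc(p0, settings.iterations, progress=False, skip_initial_state_check=True)
    chain = sampler.get_chain(discard=settings.burn_in)  # (steps, walkers, k)
    accept = float(np.mean(sampler.acceptance_fraction))

    n_ret = chain.shape[0]
    theta_by_walker = np.moveaxis(chain, 0, 1)  # (walkers, steps, k)

    # split-R̂ treating every walker as a chain
    rhat: dict[str, float] = {}
    for j, name in enumerate(sd_names):
        rhat[name] = split_rhat(np.exp(theta_by_walker[:, :, j]))

    # -- thin to stored draws and reconstitute coefficients ---------------
    flat = theta_by_walker.reshape(nwalkers * n_ret, k)
    walker_of = np.repeat(np.arange(nwalkers), n_ret)
    n_store = min(settings.max_stored_draws, len(flat))
    idx = np.linspace(0, len(flat) - 1, n_store).astype(int)
    rng_u = np.random.default_rng(spawn_seed(settings.seed, "conditional"))

    beta_cols = [f"beta[{c}]" for c in x_cols]
    re_r_cols = [f"re_region[{r}]" for r in region_levels]
    re_s_cols = [f"re_species[{r}|{s}]" for r, s in unit_levels]
    records = np.empty((n_store, k + m))
    for out_i, flat_i in enumerate(idx):
        theta = flat[flat_i]
        sds = np.exp(theta)
        sigma2 = sds[0] ** 2
        d = d_fix.copy()
        if spec.nested_random:
            d = np.concatenate([d, np.full(n_r, sds[1] ** 2), np.full(n_s, sds[2] ** 2)])
        A = WtW / sigma2 + np.diag(1.0 / d)
        LA = np.linalg.cholesky(A)
        mean = np.linalg.solve(A, Wty / sigma2)
        u = mean + np.linalg.solve(LA.T, rng_u.standard_normal(m))
        if spec.nested_random and spec.phylo:
            u = u.copy()
            u[p + n_r:] = Ls @ u[p + n_r:]  # back to actual species effects
        records[out_i, :k] = sds
        records[out_i, k:] = u

    draws = pd.DataFrame(records, columns=sd_names + beta_cols + re_r_cols + re_s_cols)
    chain_of = (walker_of[idx] * settings.chains // nwalkers).astype(int)
    draws.insert(0, "chain", chain_of)

    # split-R̂ for reconstituted parameters, grouped by originating chain
    for col in beta_cols + re_r_cols + re_s_cols:
        groups = [draws.loc[draws["chain"] == c, col].to_numpy()
                  for c in range(settings.chains)]
        width = min(len(g) for g in groups)
        if width >= 4 and settings.chains >= 2:
            rhat[col] = split_rhat(np.stack([g[:width] for g in groups]))
        else:
            rhat[col] = float("nan")

    finite_rhats = [v for v in rhat.values() if np.isfinite(v)]
    max_rhat = max(finite_rhats) if finite_rhats else float("nan")
    converged = bool(max_rhat <= RHAT_THRESHOLD)
    diagnostics = {
        "max_rhat": max_rhat,
        "converged": converged,
        "acceptance_fraction": accept,
        "divergences": 0,  # the marginalized ensemble sampler has none
        "n_obs": int(n),
    }
    if check_convergence and not converged:
        warnings.warn(
            f"fit flagged as non-converged: max split-R̂ = {max_rhat:.3f} "
            f"(threshold {RHAT_THRESHOLD})",
            NonConvergenceWarning,
            stacklevel=3,
        )

    fp_cols = sorted(set(df.columns) & {"species", "region", "group", "sex",
                                        spec.predictor, spec.response})
    return FittedGLMM(
        spec=spec,
        settings=settings,
        priors=dict(priors),
        draws=draws,
        rhat=rhat,
        diagnostics=diagnostics,
        x_cols=x_cols,
        levels=levels_with_random(levels, region_levels, unit_levels),
        species_corr=corr_all,
        data_fingerprint=data_fingerprint(df, fp_cols),
    )


def levels_with_random(levels: _Levels, region_levels, unit_levels) -> _Levels:
    return _Levels(group=levels.group, sex=levels.sex,
                   region=list(region_levels), units=list(unit_levels))


# ---------------------------------------------------------------------------
# functional wrappers


def fit_interspecific(
    data: pd.DataFrame,
    spec: ModelSpec | str = "taxo-full",
    settings: MCMCSettings | None = None,
    priors: Mapping[str, float] | None = None,
) -> FittedGLMM:
    """Fit a taxonomic GLMM; ``spec`` may be a ModelSpec or a label."""
    if isinstance(spec, str):
        spec = MODEL_LABELS[spec]
    if spec.phylo:
        raise ValueError("use fit_interspecific_phylo for phylogeny-constrained specs")
    settings = settings or MCMCSettings()
    est = AllometricGLMM(
        fixed_terms=spec.fixed_terms, nested_random=spec.nested_random,
        priors=dict(priors) if priors else None,
        iterations=settings.iterations, burn_in=settings.burn_in,
        chains=settings.chains, walkers_per_chain=settings.walkers_per_chain,
        seed=settings.seed, max_stored_draws=settings.max_stored_draws,
        response=spec.response, predictor=spec.predictor,
    )
    est.fit(data)
    return est.result_


def fit_interspecific_phylo(
    data: pd.DataFrame,
    spec: ModelSpec | str,
    tree: Phylogeny,
    settings: MCMCSettings | None = None,
    priors: Mapping[str, float] | None = None,
) -> FittedGLMM:
    """Fit the phylogenetic GLMM (species term constrained by ``tree``)."""
    if isinstance(spec, str):
        spec = MODEL_LABELS[spec]
    spec = replace(spec, phylo=True, nested_random=True)
    settings = settings or MCMCSettings()
    est = AllometricGLMM(
        fixed_terms=spec.fixed_terms, nested_random=True, tree=tree,
        priors=dict(priors) if priors else None,
        iterations=settings.iterations, burn_in=settings.burn_in,
        chains=settings.chains, walkers_per_chain=settings.walkers_per_chain,
        seed=settings.seed, max_stored_draws=settings.max_stored_draws,
        response=spec.response, predictor=spec.predictor,
    )
    est.fit(data)
    return est.result_


def predict_dry_weight(
    model: FittedGLMM | AllometricEquation,
    newdata: pd.DataFrame,
    level: float = 0.90,
    seed: int | None = None,
    include_residual: bool = False,
) -> list[PredictionResult]:
    """Per-record dry-weight predictions from a fitted model or equation."""
    if isinstance(model, AllometricEquation):
        xs = newdata[_eq_col(model)].to_numpy(dtype=float)
        return [predict_from_equation(model, float(x), level=level) for x in xs]
    rng = np.random.default_rng(seed) if seed is not None else None
    return model.predict(newdata, level=level, rng=rng,
                         include_residual=include_residual)


def _eq_col(eq: AllometricEquation) -> str:
    return eq.predictor


def predictions_frame(results: Sequence[PredictionResult]) -> pd.DataFrame:
    """Tabulate prediction results (one row per input record)."""
    return pd.DataFrame({
        "point_mg": [r.point for r in results],
        "se_mg": [r.se for r in results],
        "lo90": [r.ci_low for r in results],
        "hi90": [r.ci_high for r in results],
        "flags": [r.scale_note for r in results],
    })
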