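"""Simulation-based validation studies with known generating truth.

The headline numbers of a real multi-continent trait survey depend on
the deposited specimen data; what a synthetic validation can establish
instead is that the machinery is *correct*: the hierarchical model
recovers the generating allometric exponent with calibrated uncertainty,
grouped cross-validation ranks the generative model first, prediction
intervals attain their nominal coverage, and every closed-form oracle
(normal equations, direct RMSE, covariance geometry) is matched to
numerical precision.  These studies are run both by the test suite and
by ``scripts/acceptance.py``.

Problem sizes follow the generator defaults (40 species x 10 specimens
for recovery and calibration) with shortened chains and modest replicate
counts so a full run stays in the minutes range on one CPU.
"""

from __future__ import annotations

import warnings

import numpy as np

from .glmm import (
    MCMCSettings,
    ModelSpec,
    fit_interspecific,
    fit_interspecific_phylo,
)
from .ols import fit_ols_loglog
from .selection import grouped_kfold_split, kfold_cv, rmse
from .simulate import GeneratorTruth, generate_specimens, generate_tree, simulate_bm_trait
from .trees import graft_species_polytomies, pagels_lambda, parse_newick, phylo_covariance
from .util import spawn_seed

__all__ = [
    "beta_recovery_study",
    "cv_ranking_study",
    "calibration_study",
    "lambda_recovery_study",
    "ols_oracle_discrepancy",
    "rmse_oracle_discrepancy",
    "covariance_psd_study",
    "graft_depth_study",
    "star_tree_equivalence",
]

TRUE_BETA = 2.6  # generator default allometric exponent


def beta_recovery_study(n_seeds: int = 20, seed: int = 0,
                        iterations: int = 1200, burn_in: int = 600) -> dict:
    """Refit the generator's default world across seeds; summarize beta.

    Returns the mean posterior-median exponent, the count of seeds whose
    central 90% interval covers the truth, and the replicate count.
    """
    meds, covered = [], 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep in range(n_seeds):
            table, _ = generate_specimens(
                GeneratorTruth(seed=spawn_seed(seed, "recovery-data", rep))
            )
            fit = fit_interspecific(
                table, ModelSpec(fixed_terms=("group", "sex")),
                MCMCSettings(iterations=iterations, burn_in=burn_in,
                             seed=spawn_seed(seed, "recovery-fit", rep)),
            )
            beta = fit.beta_draws()["beta[ln_x]"].to_numpy()
            meds.append(float(np.median(beta)))
            covered += bool(np.quantile(beta, 0.05) <= TRUE_BETA <= np.quantile(beta, 0.95))
    return {
        "mean_posterior_median": float(np.mean(meds)),
        "abs_error_of_mean": float(abs(np.mean(meds) - TRUE_BETA)),
        "ci90_coverage_count": int(covered),
        "n": n_seeds,
    }


def cv_ranking_study(n_replicates: int = 10, seed: int = 0,
                     iterations: int = 400, burn_in: int = 200, k: int = 4) -> dict:
    """Does grouped K-fold CV rank the generative (sex) model first?

    Data carry a real sex offset; the sex model's K-CV total should beat
    the no-sex model's in most replicates.
    """
    wins = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep in range(n_replicates):
            table, _ = generate_specimens(GeneratorTruth(
                n_groups=2, species_per_group=10, specimens_per_species_sex=3,
                seed=spawn_seed(seed, "cv-data", rep),
            ))
            folds = grouped_kfold_split(table, k=k, seed=spawn_seed(seed, "cv-folds", rep))
            settings = MCMCSettings(iterations=iterations, burn_in=burn_in,
                                    seed=spawn_seed(seed, "cv-fit", rep))
            without = kfold_cv(ModelSpec(fixed_terms=()), table, folds, settings)
            with_sex = kfold_cv(ModelSpec(fixed_terms=("sex",)), table, folds, settings)
            wins += with_sex.total_score <= without.total_score
    return {"generative_model_ranked_first": int(wins), "n": n_replicates}


def calibration_study(n_worlds: int = 10, preds_per_world: int = 100,
                      seed: int = 0, iterations: int = 1200,
                      burn_in: int = 600) -> dict:
    """Empirical 90% interval coverage for unseen-species predictions.

    Each world is one generator realization; the model trains on the
    default 40 species and predicts specimens of new species from the
    same realized world (same region effects, new species intercepts).
    Coverage is measured against each record's true noise-free
    conditional mean.
    """
    hits = total = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for world in range(n_worlds):
            truth = GeneratorTruth(seed=spawn_seed(seed, "cal-data", world),
                                   species_per_group=20)
            table, _ = generate_specimens(truth)
            spnum = table.species.str.extract(r"sp(\d+)$")[0].astype(int)
            train = table[spnum < 10]
            test = (table[spnum >= 10].groupby("species").head(3)
                    .head(preds_per_world))
            fit = fit_interspecific(
                train, ModelSpec(fixed_terms=("group", "sex")),
                MCMCSettings(iterations=iterations, burn_in=burn_in,
                             seed=spawn_seed(seed, "cal-fit", world)),
            )
            preds = fit.predict(
                test, rng=np.random.default_rng(spawn_seed(seed, "cal-rng", world)))
            true_mg = np.exp(test["true_ln_mean"].to_numpy())
            hits += sum(p.ci_low <= m <= p.ci_high for p, m in zip(preds, true_mg))
            total += len(test)
    return {"coverage": float(hits / total), "n": int(total)}


def lambda_recovery_study(n_replicates: int = 20, seed: int = 0,
                          n_genera: int = 20, species_per_genus: int = 5) -> dict:
    """Pagel's lambda on Brownian vs shuffled traits over replicate trees."""
    rng = np.random.default_rng(spawn_seed(seed, "lambda-shuffle"))
    bm, shuffled = [], []
    for rep in range(n_replicates):
        tree, _ = generate_tree(n_genera, species_per_genus,
                                seed=spawn_seed(seed, "lambda-tree", rep))
        trait = simulate_bm_trait(tree, 1.0, 1.0,
                                  seed=spawn_seed(seed, "lambda-trait", rep))
        bm.append(pagels_lambda(tree, trait).lambda_hat)
        vals = list(trait.values())
        rng.shuffle(vals)
        shuffled.append(pagels_lambda(tree, dict(zip(trait, vals))).lambda_hat)
    return {
        "bm_median": float(np.median(bm)),
        "shuffled_median": float(np.median(shuffled)),
        "n": n_replicates,
    }


def ols_oracle_discrepancy(n_instances: int = 100, seed: int = 0) -> dict:
    """Max |difference| between the OLS fit and closed-form normal equations."""
    rng = np.random.default_rng(spawn_seed(seed, "ols-oracle"))
    worst = 0.0
    for _ in range(n_instances):
        x = np.exp(rng.normal(0.5, 0.6, size=50))
        y = np.exp(0.8 + 2.2 * np.log(x) + rng.normal(0, 0.4, size=50))
        fit = fit_ols_loglog(x, y)
        lx, ly = np.log(x), np.log(y)
        X = np.column_stack([np.ones_like(lx), lx])
        coef = np.linalg.solve(X.T @ X, X.T @ ly)
        worst = max(worst, abs(fit.alpha - coef[0]), abs(fit.beta - coef[1]))
    return {"max_abs_diff": float(worst), "n": n_instances}


def rmse_oracle_discrepancy(n: int = 1000, seed: int = 0) -> dict:
    rng = np.random.default_rng(spawn_seed(seed, "rmse-oracle"))
    o, p = rng.normal(size=n), rng.normal(size=n)
    direct = float(np.sqrt(np.mean((o - p) ** 2)))
    return {"abs_diff": float(abs(rmse(o, p) - direct)), "n": n}


def covariance_psd_study(n_trees: int = 100, seed: int = 0) -> dict:
    """Minimum eigenvalue of the phylogenetic covariance over random trees."""
    worst = np.inf
    for rep in range(n_trees):
        tree, _ = generate_tree(4 + rep % 8, 1 + rep % 3,
                                seed=spawn_seed(seed, "psd-tree", rep))
        eig = np.linalg.eigvalsh(phylo_covariance(tree).to_numpy())
        worst = min(worst, float(eig.min()))
    return {"min_eigenvalue": worst, "n": n_trees}


def graft_depth_study(n_trees: int = 50, seed: int = 0) -> dict:
    """Max relative depth distortion introduced by polytomy grafting."""
    from .simulate import generate_backbone

    worst = 0.0
    for rep in range(n_trees):
        backbone = generate_backbone(6 + rep % 10,
                                     seed=spawn_seed(seed, "graft-tree", rep))
        depth = max(backbone.tip_depths().values())
        mapping = {f"{g} sp{j}": g for g in backbone.tip_labels for j in range(3)}
        grafted, _ = graft_species_polytomies(backbone, mapping, fraction=0.4)
        for d in grafted.tip_depths().values():
            worst = max(worst, abs(d - depth) / depth)
    return {"max_rel_depth_error": float(worst), "n": n_trees}


def star_tree_equivalence(seed: int = 0, iterations: int = 600,
                          burn_in: int = 300) -> dict:
    """Max |draw difference| between star-tree PGLMM and i.i.d. GLMM."""
    table, _ = generate_specimens(GeneratorTruth(
        n_groups=2, species_per_group=8, specimens_per_species_sex=3,
        seed=spawn_seed(seed, "star-data"),
    ))
    species = sorted(table.species.unique())
    star = parse_newick("(" + ",".join(f"'{s}':1" for s in species) + ");")
    spec = ModelSpec(fixed_terms=("sex",))
    settings = MCMCSettings(iterations=iterations, burn_in=burn_in,
                            seed=spawn_seed(seed, "star-fit"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_iid = fit_interspecific(table, spec, settings)
        f_phy = fit_interspecific_phylo(table, spec, star, settings)
    cols = [c for c in f_iid.draws.columns if c != "chain"]
    diff = np.abs(f_iid.draws[cols].to_numpy() - f_phy.draws[cols].to_numpy())
    return {"max_abs_draw_diff": float(diff.max()), "n": int(f_iid.n_draws)}
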