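"""Hierarchical model fitting, prediction, and the phylogenetic variant."""

import numpy as np
import pandas as pd
import pytest

from beescale.glmm import (
    DEFAULT_PRIORS,
    AllometricGLMM,
    FittedGLMM,
    MCMCSettings,
    ModelSpec,
    NonConvergenceWarning,
    SingularDesignError,
    _Levels,
    fit_interspecific,
    fit_interspecific_phylo,
    predict_dry_weight,
    predictions_frame,
)
from beescale.simulate import GeneratorTruth, generate_specimens


class TestModelSpec:
    def test_interaction_requires_main_effect(self):
        with pytest.raises(ValueError, match="main effect"):
            ModelSpec(fixed_terms=("sex_slope",))

    def test_phylo_requires_nested_random(self):
        with pytest.raises(ValueError, match="nested"):
            ModelSpec(phylo=True, nested_random=False)

    def test_settings_invariants(self):
        with pytest.raises(ValueError):
            MCMCSettings(iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            MCMCSettings(adapt_delta=1.5)


class TestFitting:
    def test_recovers_slope_and_sex_offset(self, default_table, quick_settings):
        table, _ = default_table
        fit = fit_interspecific(table, ModelSpec(fixed_terms=("group", "sex")),
                                quick_settings)
        beta = fit.beta_draws()["beta[ln_x]"].to_numpy()
        assert np.quantile(beta, 0.05) <= 2.6 + 0.25
        assert np.quantile(beta, 0.95) >= 2.6 - 0.25
        sexoff = fit.beta_draws()["beta[sex=male]"].to_numpy()
        assert abs(np.median(sexoff) - (-0.3)) < 0.15
        assert set(fit.rhat) >= {"sigma", "sigma_region", "sigma_species"}

    def test_constant_response_intercept_only(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame({
            "species": [f"sp{i // 4}" for i in range(40)],
            "region": "Europe",
            "itd_mm": np.exp(rng.normal(0.5, 0.3, 40)),
            "dry_weight_mg": np.exp(2.0),
        })
        spec = ModelSpec(fixed_terms=(), nested_random=False)
        fit = fit_interspecific(table, spec, MCMCSettings(iterations=600, burn_in=300, seed=1))
        icpt = fit.beta_draws()["beta[Intercept]"].to_numpy()
        assert np.median(icpt) == pytest.approx(2.0, abs=0.05)
        assert np.median(fit.sigma_draws()) < 0.05

    def test_all_female_sex_model_is_singular(self, small_table, quick_settings):
        females = small_table[small_table.sex == "female"]
        with pytest.raises(SingularDesignError):
            fit_interspecific(females, ModelSpec(fixed_terms=("sex", "sex_slope")),
                              quick_settings)

    def test_needs_two_species(self, quick_settings):
        table = pd.DataFrame({
            "species": "only one", "region": "Europe",
            "itd_mm": np.linspace(1, 2, 8), "dry_weight_mg": np.linspace(5, 9, 8),
        })
        with pytest.raises(ValueError, match=">= 2 species"):
            fit_interspecific(table, ModelSpec(fixed_terms=()), quick_settings)

    def test_missing_response_reported(self, small_table, quick_settings):
        broken = small_table.copy()
        broken.loc[broken.index[:3], "dry_weight_mg"] = np.nan
        with pytest.raises(ValueError, match="lack the response"):
            fit_interspecific(broken, ModelSpec(fixed_terms=()), quick_settings)

    def test_reproducible_given_seed(self, small_table, quick_settings):
        f1 = fit_interspecific(small_table, ModelSpec(fixed_terms=("sex",)), quick_settings)
        f2 = fit_interspecific(small_table, ModelSpec(fixed_terms=("sex",)), quick_settings)
        pd.testing.assert_frame_equal(f1.draws, f2.draws)

    def test_nonconvergence_is_flagged_not_silent(self, small_table):
        tight = MCMCSettings(iterations=30, burn_in=10, seed=1)
        with pytest.warns(NonConvergenceWarning):
            fit = fit_interspecific(small_table, ModelSpec(fixed_terms=("sex",)), tight)
        assert not fit.converged

    def test_sklearn_estimator_contract(self, small_table):
        est = AllometricGLMM(fixed_terms=("sex",), iterations=400, burn_in=200, seed=3)
        params = est.get_params()
        assert params["fixed_terms"] == ("sex",)
        est.set_params(seed=5).fit(small_table)
        assert hasattr(est, "result_") and hasattr(est, "converged_")
        pts = est.predict(small_table.head(5))
        assert pts.shape == (5,) and np.all(pts > 0)
        band = est.predict_interval(small_table.head(5))
        assert list(band.columns) == ["point_mg", "se_mg", "lo90", "hi90", "flags"]


def _fixed_effect_model(lnalpha=1.0, beta=2.0, sigma=1e-9, n_draws=50):
    """Hand-built posterior with point-mass coefficients, for closed forms."""
    draws = pd.DataFrame({
        "chain": np.zeros(n_draws, dtype=int),
        "sigma": np.full(n_draws, sigma),
        "beta[Intercept]": np.full(n_draws, lnalpha),
        "beta[ln_x]": np.full(n_draws, beta),
    })
    return FittedGLMM(
        spec=ModelSpec(fixed_terms=(), nested_random=False),
        settings=MCMCSettings(iterations=100, burn_in=50, seed=1),
        priors=dict(DEFAULT_PRIORS),
        draws=draws, rhat={}, diagnostics={"converged": True},
        x_cols=["Intercept", "ln_x"],
        levels=_Levels(group=[], sex=[], region=[], units=[]),
        species_corr=None, data_fingerprint="handmade",
    )


class TestPrediction:
    def test_closed_form_points(self):
        model = _fixed_effect_model()
        preds = model.predict(pd.DataFrame({"itd_mm": [1.0, 2.0]}))
        assert preds[0].point == pytest.approx(np.e, rel=1e-9)       # x=1: e^1
        assert preds[1].point == pytest.approx(np.exp(1 + 2 * np.log(2)), rel=1e-9)

    def test_monotone_in_itd(self, small_table, quick_settings):
        fit = fit_interspecific(small_table, ModelSpec(fixed_terms=("sex",)),
                                quick_settings)
        sp = small_table.iloc[0]
        grid = pd.DataFrame({
            "itd_mm": np.linspace(0.5, 6.0, 15),
            "sex": sp.sex, "region": sp.region, "species": sp.species,
        })
        pts = np.array([p.point for p in fit.predict(grid)])
        assert np.all(np.diff(pts) > 0)

    def test_log_linearity_of_fixed_effect_model(self):
        truth = GeneratorTruth(n_groups=1, lnalpha_by_group=(1.0,),
                               beta_by_group=(2.6,), region_sd=0.0,
                               species_sd=0.0, seed=5)
        table, _ = generate_specimens(truth)
        fit = fit_interspecific(table, ModelSpec(fixed_terms=(), nested_random=False),
                                MCMCSettings(iterations=600, burn_in=300, seed=3))
        lx = np.log(np.geomspace(0.5, 8, 12))
        pts = np.array([p.point for p in fit.predict(pd.DataFrame({"itd_mm": np.exp(lx)}))])
        lp = np.log(pts)
        resid = lp - np.polyval(np.polyfit(lx, lp, 1), lx)
        assert np.abs(resid).max() < 0.01

    def test_interval_brackets_point_and_se_positive(self, small_table, quick_settings):
        fit = fit_interspecific(small_table, ModelSpec(fixed_terms=("sex",)),
                                quick_settings)
        for p in fit.predict(small_table.head(10)):
            assert 0 < p.ci_low <= p.point <= p.ci_high
            assert p.se > 0

    def test_unseen_region_warns_and_widens(self, small_table, quick_settings):
        fit = fit_interspecific(small_table, ModelSpec(fixed_terms=("sex",)),
                                quick_settings)
        seen = small_table.iloc[[0]][["itd_mm", "sex", "region", "species"]]
        unseen = seen.assign(region="South America", species="novel species")
        with pytest.warns(UserWarning, match="South America"):
            p_unseen = fit.predict(unseen, rng=np.random.default_rng(0))[0]
        p_seen = fit.predict(seen, rng=np.random.default_rng(0))[0]
        assert p_unseen.ci_high / p_unseen.ci_low > p_seen.ci_high / p_seen.ci_low

    def test_unseen_group_is_an_error(self, small_table, quick_settings):
        fit = fit_interspecific(small_table, ModelSpec(fixed_terms=("group", "sex")),
                                quick_settings)
        bad = small_table.iloc[[0]].assign(group="Stenotritidae")
        with pytest.raises(ValueError, match="Stenotritidae"):
            fit.predict(bad)

    def test_nonpositive_itd_rejected(self):
        model = _fixed_effect_model()
        with pytest.raises(ValueError, match="positive"):
            model.predict(pd.DataFrame({"itd_mm": [-1.0]}))

    def test_predict_dry_weight_dispatches_to_equation(self):
        from beescale.registry import load_packaged_registry
        eq = next(e for e in load_packaged_registry() if e.eq_id == "cane1987_bee_itd")
        preds = predict_dry_weight(eq, pd.DataFrame({"itd_mm": [0.77]}))
        assert preds[0].point == pytest.approx(1.0, rel=1e-9)

    def test_predictions_frame_layout(self):
        model = _fixed_effect_model()
        frame = predictions_frame(model.predict(pd.DataFrame({"itd_mm": [1.0]})))
        assert list(frame.columns) == ["point_mg", "se_mg", "lo90", "hi90", "flags"]


class TestSerialization:
    def test_roundtrip_preserves_predictions(self, small_table, quick_settings, tmp_path):
        fit = fit_interspecific(small_table, ModelSpec(fixed_terms=("sex",)),
                                quick_settings)
        fit.to_dir(tmp_path / "m")
        back = FittedGLMM.from_dir(tmp_path / "m")
        new = small_table.head(8)
        p1 = [p.point for p in fit.predict(new, rng=np.random.default_rng(1))]
        p2 = [p.point for p in back.predict(new, rng=np.random.default_rng(1))]
        assert p1 == pytest.approx(p2, rel=1e-12)
        assert back.data_fingerprint == fit.data_fingerprint


class TestPhyloVariant:
    @staticmethod
    def _star_tree(species):
        from beescale.trees import parse_newick
        return parse_newick("(" + ",".join(f"'{s}':1" for s in species) + ");")

    def test_star_tree_matches_iid_fit(self, small_table, quick_settings):
        """Star phylogeny = diagonal covariance: identical posterior draws."""
        star = self._star_tree(sorted(small_table.species.unique()))
        spec = ModelSpec(fixed_terms=("sex",))
        f_iid = fit_interspecific(small_table, spec, quick_settings)
        f_phy = fit_interspecific_phylo(small_table, spec, star, quick_settings)
        cols = [c for c in f_iid.draws.columns if c != "chain"]
        diff = np.abs(f_iid.draws[cols].to_numpy() - f_phy.draws[cols].to_numpy())
        assert diff.max() < 1e-8

    def test_species_missing_from_tree_are_named(self, small_table, quick_settings):
        species = sorted(small_table.species.unique())
        star = self._star_tree(species[:-2])
        with pytest.raises(ValueError) as exc:
            fit_interspecific_phylo(small_table, ModelSpec(fixed_terms=("sex",)),
                                    star, quick_settings)
        assert species[-1] in str(exc.value)
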