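"""Bayesian R^2, grouped K-fold CV, RMSE, and the comparison table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from beescale.glmm import MCMCSettings, ModelSpec, fit_interspecific
from beescale.selection import (
    bayes_r2,
    compare_models,
    comparison_to_frame,
    comparison_to_markdown,
    grouped_kfold_split,
    kfold_cv,
    rmse,
)
from beescale.simulate import GeneratorTruth, generate_specimens


class TestGroupedKfold:
    @staticmethod
    def _table(n_species):
        return pd.DataFrame({"species": [f"sp{i}" for i in range(n_species)] * 2})

    def test_even_split(self):
        folds = grouped_kfold_split(self._table(20), k=10, seed=1)
        sizes = pd.Series(folds).value_counts()
        assert len(sizes) == 10 and set(sizes) == {2}

    def test_uneven_split_differs_by_at_most_one(self):
        folds = grouped_kfold_split(self._table(23), k=10, seed=1)
        sizes = pd.Series(folds).value_counts()
        assert set(sizes).issubset({2, 3})

    def test_deterministic_and_order_invariant(self):
        tab = self._table(17)
        f1 = grouped_kfold_split(tab, k=5, seed=9)
        f2 = grouped_kfold_split(tab.sample(frac=1, random_state=3), k=5, seed=9)
        assert f1 == f2

    def test_k_exceeding_groups_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            grouped_kfold_split(self._table(5), k=10, seed=0)

    @given(n=st.integers(6, 60), k=st.integers(2, 6), seed=st.integers(0, 10))
    def test_partition_property(self, n, k, seed):
        tab = self._table(n)
        folds = grouped_kfold_split(tab, k=k, seed=seed)
        assert set(folds) == set(tab.species.unique())      # every species once
        sizes = pd.Series(folds).value_counts()
        assert sizes.max() - sizes.min() <= 1


class TestRmse:
    def test_identical_vectors_give_zero(self):
        assert rmse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_constant_offset(self):
        obs = np.arange(5.0)
        assert rmse(obs, obs + 2.5) == pytest.approx(2.5)
        assert rmse(obs, obs - 2.5) == pytest.approx(2.5)  # sign-symmetric

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(4)
        o, p = rng.normal(size=1000), rng.normal(size=1000)
        assert rmse(o, p) == pytest.approx(float(np.sqrt(np.mean((o - p) ** 2))),
                                           abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmse([1.0, 2.0], [1.0])


class TestBayesR2:
    def test_signal_dominated_limit(self):
        truth = GeneratorTruth(n_groups=2, species_per_group=8,
                               specimens_per_species_sex=3, resid_sd=0.01,
                               region_sd=0.0, species_sd=0.01, seed=4)
        table, _ = generate_specimens(truth)
        fit = fit_interspecific(table, ModelSpec(fixed_terms=("sex",)),
                                MCMCSettings(iterations=500, burn_in=250, seed=2))
        assert bayes_r2(fit, table)["mean"] > 0.99

    def test_slope_free_data_scores_near_zero(self):
        rng = np.random.default_rng(8)
        table = pd.DataFrame({
            "species": [f"sp{i // 6}" for i in range(120)],
            "region": "Europe",
            "sex": ["female", "male"] * 60,
            "itd_mm": np.exp(rng.normal(0.7, 0.4, 120)),
            "dry_weight_mg": np.exp(rng.normal(2.0, 0.5, 120)),  # no ITD signal
        })
        spec = ModelSpec(fixed_terms=(), nested_random=False)
        fit = fit_interspecific(table, spec, MCMCSettings(iterations=500, burn_in=250, seed=2))
        assert bayes_r2(fit, table)["mean"] < 0.15

    def test_draws_bounded_and_relabel_invariant(self, small_table, quick_settings):
        fit = fit_interspecific(small_table, ModelSpec(fixed_terms=("sex",)),
                                quick_settings)
        out = bayes_r2(fit, small_table)
        assert np.all((out["draws"] >= 0) & (out["draws"] <= 1))
        shuffled = small_table.sample(frac=1, random_state=5)
        assert bayes_r2(fit, shuffled)["mean"] == pytest.approx(out["mean"], abs=1e-12)


class TestKfoldCV:
    def test_deterministic_given_seeds(self, small_table):
        folds = grouped_kfold_split(small_table, k=4, seed=2)
        st_ = MCMCSettings(iterations=300, burn_in=150, seed=5)
        a = kfold_cv(ModelSpec(fixed_terms=("sex",)), small_table, folds, st_)
        b = kfold_cv(ModelSpec(fixed_terms=("sex",)), small_table, folds, st_)
        assert a.total_score == b.total_score
        assert a.fold_scores == b.fold_scores
        assert a.total_score == pytest.approx(sum(a.fold_scores))

    def test_single_fold_rejected(self, small_table):
        folds = dict.fromkeys(small_table.species.unique(), 0)
        with pytest.raises(ValueError, match="2 folds"):
            kfold_cv(ModelSpec(fixed_terms=()), small_table, folds,
                     MCMCSettings(iterations=300, burn_in=150, seed=1))

    def test_unassigned_species_rejected(self, small_table):
        folds = grouped_kfold_split(small_table, k=4, seed=2)
        folds.pop(sorted(folds)[0])
        with pytest.raises(ValueError, match="without a fold"):
            kfold_cv(ModelSpec(fixed_terms=()), small_table, folds,
                     MCMCSettings(iterations=300, burn_in=150, seed=1))


class TestCompareModels:
    def test_single_model_has_zero_delta(self, small_table):
        st_ = MCMCSettings(iterations=300, burn_in=150, seed=5)
        fit = fit_interspecific(small_table, ModelSpec(fixed_terms=("sex",)), st_)
        folds = grouped_kfold_split(small_table, k=4, seed=2)
        rows = compare_models([fit], small_table, folds)
        assert rows[0].delta_kcv == 0.0
        assert rows[0].rmse_mg > 0

    def test_mixed_fingerprints_rejected(self, small_table):
        st_ = MCMCSettings(iterations=300, burn_in=150, seed=5)
        f1 = fit_interspecific(small_table, ModelSpec(fixed_terms=("sex",)), st_)
        f2 = fit_interspecific(small_table.head(60), ModelSpec(fixed_terms=("sex",)), st_)
        folds = grouped_kfold_split(small_table, k=4, seed=2)
        with pytest.raises(ValueError, match="fingerprint"):
            compare_models([f1, f2], small_table, folds)

    def test_exports(self, small_table):
        st_ = MCMCSettings(iterations=300, burn_in=150, seed=5)
        fit = fit_interspecific(small_table, ModelSpec(fixed_terms=("sex",)), st_)
        folds = grouped_kfold_split(small_table, k=4, seed=2)
        rows = compare_models([fit], small_table, folds)
        frame = comparison_to_frame(rows)
        assert list(frame.columns) == ["model", "bayes_r2", "kcv", "delta_kcv",
                                       "rmse_mg", "unreliable"]
        md = comparison_to_markdown(rows)
        assert md.startswith("| Model |") and rows[0].label in md
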