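"""Tree I/O, backbone surgery, chronograms, covariance, and Pagel's lambda."""

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from beescale.simulate import generate_backbone, generate_tree, simulate_bm_trait
from beescale.trees import (
    chronogram_pl,
    graft_species_polytomies,
    pagels_lambda,
    parse_newick,
    phylo_covariance,
    prune_to_genera,
    read_newick,
    to_newick,
    write_newick,
)


class TestNewickIO:
    def test_two_tip_tree(self):
        t = parse_newick("(A:1,B:1);")
        assert sorted(t.tip_labels) == ["A", "B"]
        assert t.tip_depths() == {"A": 1.0, "B": 1.0}

    def test_duplicate_tips_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            parse_newick("(A:1,A:2);")

    def test_malformed_newick_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            parse_newick("(A:1,B:1")

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            parse_newick("(A:1,B:-0.5);")

    def test_roundtrip_topology_and_lengths(self, tmp_path):
        """Write-then-read of a random 50-tip tree: RF distance 0, lengths kept."""
        tree = generate_backbone(50, seed=9)
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        back = read_newick(path)
        tns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=to_newick(tree), schema="newick",
                               taxon_namespace=tns, preserve_underscores=True)
        t2 = dendropy.Tree.get(data=to_newick(back), schema="newick",
                               taxon_namespace=tns, preserve_underscores=True)
        assert treecompare.symmetric_difference(t1, t2) == 0
        d1, d2 = tree.tip_depths(), back.tip_depths()
        assert all(d2[k] == pytest.approx(d1[k], rel=1e-12) for k in d1)


class TestPrune:
    def test_keep_all_is_identity(self):
        tree = parse_newick("((A:1,B:2):1,C:3);")
        out = prune_to_genera(tree, {"A", "B", "C"})
        assert out.tip_depths() == tree.tip_depths()

    def test_path_length_preserved(self):
        tree = parse_newick("(((A:1,B:1):1,(C:1,D:1):2):1,E:5);")
        out = prune_to_genera(tree, {"A", "E"})
        assert sorted(out.tip_labels) == ["A", "E"]
        # patristic A-E in the backbone: 1+1+1 + 5 = 8
        d = out.tip_depths()
        assert d["A"] + d["E"] == pytest.approx(8.0)

    def test_keep_none_rejected(self):
        with pytest.raises(ValueError, match="no genera"):
            prune_to_genera(parse_newick("(A:1,B:1);"), set())

    def test_unknown_genus_rejected(self):
        with pytest.raises(ValueError, match="not in backbone"):
            prune_to_genera(parse_newick("(A:1,B:1);"), {"Z"})


class TestGraft:
    def test_single_species_relabels_tip(self):
        bb = parse_newick("(X:10,Y:10);")
        out, excluded = graft_species_polytomies(bb, {"X alpha": "X", "Y beta": "Y"})
        assert excluded == []
        assert out.tip_depths() == {"X alpha": 10.0, "Y beta": 10.0}

    def test_polytomy_geometry_default_fraction(self):
        """Genus edge 10, 3 species: tips at 5 below a stem of 5."""
        bb = parse_newick("(X:10,Y:10);")
        out, _ = graft_species_polytomies(
            bb, {"X a": "X", "X b": "X", "X c": "X", "Y a": "Y"})
        depths = out.tip_depths()
        assert depths == {"X a": 10.0, "X b": 10.0, "X c": 10.0, "Y a": 10.0}
        cov = phylo_covariance(out)
        # congeners: pairwise patristic distance 2 * 5
        for a, b in [("X a", "X b"), ("X a", "X c"), ("X b", "X c")]:
            assert cov.loc[a, a] + cov.loc[b, b] - 2 * cov.loc[a, b] == pytest.approx(10.0)

    def test_unplaced_genus_goes_to_excluded_list(self):
        bb = parse_newick("(X:10,Y:10);")
        out, excluded = graft_species_polytomies(
            bb, {"X a": "X", "Flavipanurgus venustus": "Flavipanurgus"})
        assert excluded == ["Flavipanurgus venustus"]
        assert "Flavipanurgus venustus" not in out.tip_labels

    def test_empty_mapping_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            graft_species_polytomies(parse_newick("(X:1,Y:1);"), {})

    @pytest.mark.parametrize("seed", range(5))
    def test_depth_preservation_random_backbones(self, seed):
        bb = generate_backbone(12, seed=seed)
        depth_in = max(bb.tip_depths().values())
        mapping = {f"{g} sp{j}": g for g in bb.tip_labels for j in range(3)}
        out, _ = graft_species_polytomies(bb, mapping, fraction=0.3)
        for d in out.tip_depths().values():
            assert d == pytest.approx(depth_in, rel=1e-9)

    def test_congeners_share_identical_off_diagonals(self):
        tree, _ = generate_tree(6, 4, seed=2)
        cov = phylo_covariance(tree)
        genera = {lab.split()[0] for lab in tree.tip_labels}
        for g in genera:
            members = [l for l in tree.tip_labels if l.startswith(g + " ")]
            vals = {round(cov.loc[a, b], 12)
                    for i, a in enumerate(members) for b in members[i + 1:]}
            assert len(vals) == 1  # all congeneric pairs identical


class TestPhyloCovariance:
    def test_star_tree_is_diagonal(self):
        t = parse_newick("(A:1,B:1,C:1,D:1);")
        cov = phylo_covariance(t).to_numpy()
        assert np.allclose(cov, np.eye(4))

    def test_three_tip_values(self):
        cov = phylo_covariance(parse_newick("((A:1,B:1):1,C:2);"))
        assert cov.loc["A", "B"] == 1.0
        assert cov.loc["A", "C"] == 0.0
        assert cov.loc["A", "A"] == 2.0

    @pytest.mark.parametrize("seed", range(20))
    def test_psd_on_random_trees(self, seed):
        tree, _ = generate_tree(4 + seed % 6, 1 + seed % 3, seed=seed)
        eig = np.linalg.eigvalsh(phylo_covariance(tree).to_numpy())
        assert eig.min() >= -1e-9


class TestChronogram:
    def test_clock_tree_recovers_proportional_depths(self):
        tree = generate_backbone(10, seed=3)
        out = chronogram_pl(tree, smoothing=1.0)
        assert out.is_ultrametric
        # input is ultrametric with unit depth: output covariance must match
        c_in = phylo_covariance(tree).to_numpy()
        c_out = phylo_covariance(out).to_numpy()
        assert np.allclose(c_in, c_out, atol=5e-3)
        assert float(np.var(out.pl_rates)) < 1e-6

    def test_large_smoothing_approaches_global_clock(self):
        tree = parse_newick("((A:4,B:1):1,(C:2,D:3):2);")
        out = chronogram_pl(tree, smoothing=1e3)
        rates = out.pl_rates
        assert np.ptp(rates) / np.mean(rates) < 0.01

    def test_two_tip_tree_is_ultrametric(self):
        out = chronogram_pl(parse_newick("(A:4,B:1);"), smoothing=1.0)
        d = out.tip_depths()
        assert d["A"] == pytest.approx(d["B"])

    def test_objective_trace_never_decreases(self):
        tree = parse_newick("(((A:3,B:1):2,C:4):1,(D:2,E:5):3);")
        out = chronogram_pl(tree, smoothing=1.0)
        trace = np.asarray(out.pl_objective_trace)
        assert np.all(np.diff(trace) >= -1e-6)

    def test_nonpositive_smoothing_rejected(self):
        with pytest.raises(ValueError):
            chronogram_pl(parse_newick("(A:1,B:1);"), smoothing=0.0)


class TestPagelsLambda:
    def test_matches_independent_ml_oracle(self):
        """Frozen oracle values from an independent ML implementation
        (phytools::phylosig) on the identical tree and trait."""
        tree, _ = generate_tree(15, 3, seed=5)
        trait = simulate_bm_trait(tree, sigma2=1.0, lambda_true=0.8, seed=6)
        res = pagels_lambda(tree, trait)
        assert res.lambda_hat == pytest.approx(0.9162396, abs=1e-4)
        assert res.loglik_at_hat == pytest.approx(-45.31898, abs=1e-3)
        assert res.loglik_at_zero == pytest.approx(-71.35422, abs=1e-3)

    def test_brownian_trait_recovers_high_lambda(self):
        lams = []
        for rep in range(10):
            tree, _ = generate_tree(20, 5, seed=rep + 300)
            trait = simulate_bm_trait(tree, 1.0, 1.0, seed=rep + 400)
            lams.append(pagels_lambda(tree, trait).lambda_hat)
        assert np.median(lams) >= 0.9

    def test_shuffled_trait_destroys_signal(self):
        rng = np.random.default_rng(0)
        lams, ps = [], []
        for rep in range(10):
            tree, _ = generate_tree(20, 5, seed=rep + 300)
            trait = simulate_bm_trait(tree, 1.0, 1.0, seed=rep + 400)
            vals = list(trait.values())
            rng.shuffle(vals)
            res = pagels_lambda(tree, dict(zip(trait.keys(), vals)))
            lams.append(res.lambda_hat)
            ps.append(res.lr_pvalue)
        assert np.median(lams) <= 0.1
        assert np.median(ps) > 0.05

    def test_affine_invariance(self):
        tree, _ = generate_tree(15, 3, seed=5)
        trait = simulate_bm_trait(tree, 1.0, 0.8, seed=6)
        base = pagels_lambda(tree, trait).lambda_hat
        shifted = pagels_lambda(tree, {k: 3.7 * v - 11.0 for k, v in trait.items()})
        assert shifted.lambda_hat == pytest.approx(base, abs=1e-5)

    def test_loglik_ordering_and_pvalue(self):
        tree, _ = generate_tree(15, 3, seed=5)
        trait = simulate_bm_trait(tree, 1.0, 0.8, seed=6)
        res = pagels_lambda(tree, trait)
        assert res.loglik_at_hat >= res.loglik_at_zero
        assert 0 <= res.lr_pvalue <= 1
        mix = pagels_lambda(tree, trait, boundary_mixture=True)
        assert mix.lr_pvalue == pytest.approx(res.lr_pvalue / 2, rel=1e-9)

    def test_non_ultrametric_tree_is_an_error(self):
        t = parse_newick("((A:4,B:1):1,(C:2,D:3):2);")
        trait = {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}
        with pytest.raises(ValueError, match="ultrametric"):
            pagels_lambda(t, trait)

    def test_too_few_tips_rejected(self):
        t = parse_newick("((A:1,B:1):1,C:2);")
        with pytest.raises(ValueError, match=">= 4"):
            pagels_lambda(t, {"A": 1.0, "B": 2.0, "C": 3.0})

    def test_trait_species_must_be_tips(self):
        tree, _ = generate_tree(5, 2, seed=1)
        trait = dict.fromkeys(list(tree.tip_labels)[:5], 1.0)
        trait["Missingus specius"] = 2.0
        with pytest.raises(ValueError, match="Missingus specius"):
            pagels_lambda(tree, trait)
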