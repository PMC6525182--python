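"""Tests for tree handling and phylogenetic comparative statistics.

The fixture tree and trait values below were cross-checked against an
independent reference implementation (ape/phytools/picante/nlme in R);
the expected numbers are frozen here so the suite runs self-contained.
"""

import numpy as np
import pandas as pd
import pytest

from rootallometry.phylo import (
    PhyloError,
    blomberg_k,
    lambda_transform,
    pagel_lambda_ml,
    pgls,
    pic,
    pic_regression,
    read_newick,
    reconcile_species,
    resolve_polytomies,
    simulate_bm_trait,
    simulate_tree,
    tip_labels,
    vcv_matrix,
    write_newick,
)

FIXTURE_NEWICK = (
    "((((t1:0.3,t2:0.3):0.7,(t3:0.5,t4:0.5):0.5):0.4,"
    "(t5:0.9,(t6:0.4,t7:0.4):0.5):0.5):0.6,((t8:0.8,t9:0.8):0.7,t10:1.5):0.5);"
)
FIXTURE_X = {
    "t1": 1.2, "t2": 1.5, "t3": 0.8, "t4": 1.1, "t5": 2.3,
    "t6": 2.0, "t7": 2.1, "t8": 0.2, "t9": 0.5, "t10": 0.9,
}
FIXTURE_Y = {
    "t1": 2.6, "t2": 3.1, "t3": 1.9, "t4": 2.2, "t5": 4.4,
    "t6": 4.1, "t7": 4.5, "t8": 0.9, "t9": 1.4, "t10": 2.2,
}
# reference values from ape::pic on the fixture (absolute contrasts)
REF_PIC_X_ABS = sorted(
    [0.7061682047, 0.7855494575, 0.3162277660, 0.3872983346, 0.3000000000,
     0.1976423538, 0.1118033989, 0.3410955201, 0.2371708245]
)
REF_K = 1.6988745190  # phytools::phylosig and picante::Kcalc agree
# profiled Gaussian log-likelihood of FIXTURE_X at fixed lambda values
REF_LAMBDA_LOGLIK = {
    0.00: -10.1566859925,
    0.25: -9.2450334735,
    0.50: -8.3653443326,
    0.75: -7.4488302457,
    1.00: -6.4228618991,
}
REF_PGLS_SLOPE = 1.7352428171  # nlme::gls with Brownian correlation
REF_PGLS_INTERCEPT = 0.5498205963
REF_PGLS_SE = (0.1836497750, 0.1244905802)


@pytest.fixture()
def fixture_tree():
    return read_newick(FIXTURE_NEWICK)


class TestNewickIO:
    def test_parse_structure(self):
        tree = read_newick("((a:1,b:1):1,c:2);")
        assert sorted(tip_labels(tree)) == ["a", "b", "c"]
        assert len(tree.seed_node.child_nodes()) == 2

    def test_round_trip_preserves_lengths(self):
        rng_trees = [simulate_tree(n, seed=s) for n, s in [(8, 1), (20, 2)]]
        for tree in rng_trees:
            again = read_newick(write_newick(tree))
            C1, lab1 = vcv_matrix(tree)
            C2, lab2 = vcv_matrix(again)
            assert lab1 == lab2
            assert np.allclose(C1, C2, atol=1e-9)

    def test_missing_branch_length_named(self):
        with pytest.raises(PhyloError, match="branch length"):
            read_newick("((a:1,b):1,c:2);")

    def test_malformed_input(self):
        with pytest.raises(PhyloError):
            read_newick("((a:1,b:1:1,c)")


class TestResolvePolytomies:
    def test_becomes_binary_and_conserves_length(self):
        tree = read_newick("(a:1,b:1,c:1,d:1);")
        total = sum(e.length or 0 for e in tree.edges())
        res = resolve_polytomies(tree, seed=3)
        for node in res.preorder_internal_node_iter():
            assert len(node.child_nodes()) == 2
        assert sum(e.length or 0 for e in res.edges()) == pytest.approx(total)

    def test_deterministic_per_seed(self):
        tree = read_newick("(a:1,b:1,c:1);")
        s1 = write_newick(resolve_polytomies(tree, seed=5))
        s2 = write_newick(resolve_polytomies(tree, seed=5))
        assert s1 == s2

    def test_binary_tree_unchanged(self):
        tree = read_newick("((a:1,b:1):1,c:2);")
        C1, _ = vcv_matrix(tree)
        C2, _ = vcv_matrix(resolve_polytomies(tree, seed=1))
        assert np.allclose(C1, C2)

    def test_tip_depths_unchanged(self, fixture_tree):
        poly = read_newick("((a:1,b:1,c:1):1,(d:0.5,e:0.5,f:0.5):1.5);")
        C1, lab1 = vcv_matrix(poly)
        res = resolve_polytomies(poly, seed=9)
        C2, lab2 = vcv_matrix(res)
        d1 = dict(zip(lab1, np.diag(C1)))
        d2 = dict(zip(lab2, np.diag(C2)))
        assert d1 == pytest.approx(d2)


class TestSimulateTree:
    def test_two_tips_is_a_cherry(self):
        tree = simulate_tree(2, seed=1)
        assert len(tip_labels(tree)) == 2

    def test_seed_reproducibility(self):
        assert write_newick(simulate_tree(12, seed=4)) == write_newick(
            simulate_tree(12, seed=4)
        )

    def test_higher_birth_rate_means_shallower_trees(self):
        depths = {}
        for rate in (1.0, 4.0):
            vals = []
            for s in range(30):
                C, _ = vcv_matrix(simulate_tree(16, seed=s, birth_rate=rate))
                vals.append(np.diag(C).mean())
            depths[rate] = np.mean(vals)
        assert depths[4.0] < depths[1.0]


class TestVcv:
    def test_two_tip_star(self):
        C, labels = vcv_matrix(read_newick("(a:1,b:1);"))
        assert np.allclose(C, np.eye(2))

    def test_hand_traced_example(self):
        C, labels = vcv_matrix(read_newick("((a:1,b:1):1,c:2);"))
        idx = {lab: i for i, lab in enumerate(labels)}
        assert C[idx["a"], idx["b"]] == pytest.approx(1.0)
        assert C[idx["a"], idx["a"]] == pytest.approx(2.0)
        assert C[idx["a"], idx["c"]] == pytest.approx(0.0)

    def test_fixture_entries_match_reference(self, fixture_tree):
        C, labels = vcv_matrix(fixture_tree)
        idx = {lab: i for i, lab in enumerate(labels)}
        assert C[idx["t1"], idx["t2"]] == pytest.approx(1.7)
        assert C[idx["t1"], idx["t1"]] == pytest.approx(2.0)
        assert C[idx["t1"], idx["t10"]] == pytest.approx(0.0)

    def test_ultrametric_constant_diagonal(self):
        C, _ = vcv_matrix(simulate_tree(20, seed=6))
        assert np.allclose(np.diag(C), C[0, 0])

    def test_lambda_transform_preserves_diagonal(self):
        C, _ = vcv_matrix(simulate_tree(10, seed=2))
        Cl = lambda_transform(C, 0.3)
        assert np.allclose(np.diag(Cl), np.diag(C))
        off = ~np.eye(len(C), dtype=bool)
        assert np.allclose(Cl[off], 0.3 * C[off])


class TestSimulateBM:
    def test_zero_rate_collapses_to_root(self, fixture_tree):
        vals = simulate_bm_trait(fixture_tree, sigma2=0.0, root_value=2.5, seed=1)
        assert np.allclose(vals, 2.5)

    def test_lambda_zero_variance_tracks_depth(self):
        tree = read_newick("((a:1,b:1):1,c:2);")
        draws = np.array(
            [
                simulate_bm_trait(tree, sigma2=1.0, lam=0.0, seed=s).to_numpy()
                for s in range(4000)
            ]
        )
        cov = np.cov(draws.T)
        assert np.allclose(np.diag(cov), 2.0, atol=0.2)
        assert abs(cov[0, 1]) < 0.1  # independent despite shared history

    def test_sample_covariance_matches_sigma2_C(self):
        tree = simulate_tree(6, seed=3)
        C, labels = vcv_matrix(tree)
        draws = np.array(
            [
                simulate_bm_trait(tree, sigma2=0.5, seed=s)
                .reindex(labels)
                .to_numpy()
                for s in range(3000)
            ]
        )
        cov = np.cov(draws.T)
        assert np.allclose(cov, 0.5 * C, atol=0.15 * max(1.0, C.max()))


class TestPIC:
    def test_cherry_closed_form(self):
        tree = read_newick("(a:1,b:1);")
        res = pic(tree, {"a": 3.0, "b": 1.0})
        assert res.contrasts == pytest.approx([2.0 / np.sqrt(2.0)])
        assert res.expected_sd == pytest.approx([np.sqrt(2.0)])

    def test_constant_trait_zero_contrasts(self, fixture_tree):
        res = pic(fixture_tree, {t: 1.0 for t in FIXTURE_X})
        assert np.allclose(res.contrasts, 0.0)
        assert res.n == 9

    def test_matches_reference_implementation(self, fixture_tree):
        res = pic(fixture_tree, FIXTURE_X)
        assert sorted(np.abs(res.contrasts)) == pytest.approx(
            REF_PIC_X_ABS, abs=1e-9
        )

    def test_missing_species_listed(self, fixture_tree):
        trait = dict(FIXTURE_X)
        del trait["t3"]
        with pytest.raises(PhyloError, match="t3"):
            pic(fixture_tree, trait)

    def test_contrast_variance_calibrated_under_bm(self):
        vars_ = []
        for s in range(300):
            tree = simulate_tree(16, seed=s)
            z = simulate_bm_trait(tree, sigma2=2.0, seed=1000 + s)
            vars_.append(np.mean(pic(tree, z).contrasts ** 2))
        assert np.mean(vars_) == pytest.approx(2.0, rel=0.1)


class TestPicRegression:
    def test_proportional_traits(self, fixture_tree):
        y = {k: 2.0 * v for k, v in FIXTURE_X.items()}
        res = pic_regression(fixture_tree, FIXTURE_X, y)
        assert res.slope == pytest.approx(2.0)
        assert res.r == pytest.approx(1.0)

    def test_matches_reference_slope(self, fixture_tree):
        res = pic_regression(fixture_tree, FIXTURE_X, FIXTURE_Y)
        assert res.slope == pytest.approx(REF_PGLS_SLOPE, abs=1e-9)

    def test_independent_traits_centered_on_zero(self):
        slopes = []
        for s in range(200):
            tree = simulate_tree(24, seed=s)
            x = simulate_bm_trait(tree, 1.0, seed=2000 + s)
            y = simulate_bm_trait(tree, 1.0, seed=5000 + s)
            slopes.append(pic_regression(tree, x, y).slope)
        assert abs(np.mean(slopes)) < 0.05


class TestBlombergK:
    def test_matches_reference_value(self, fixture_tree):
        res = blomberg_k(fixture_tree, FIXTURE_X, n_permutations=199, seed=0)
        assert res.estimate == pytest.approx(REF_K, abs=1e-9)
        assert 0 < res.p_value <= 1

    def test_constant_trait_rejected(self, fixture_tree):
        with pytest.raises(PhyloError):
            blomberg_k(fixture_tree, {t: 2.0 for t in FIXTURE_X})

    def test_shuffled_trait_loses_signal(self):
        tree = simulate_tree(80, seed=12)
        z = simulate_bm_trait(tree, 1.0, seed=13)
        shuffled = pd.Series(
            np.random.default_rng(0).permutation(z.to_numpy()), index=z.index
        )
        k_bm = blomberg_k(tree, z, n_permutations=0).estimate
        k_shuf = blomberg_k(tree, shuffled, n_permutations=199, seed=1)
        assert k_shuf.estimate < min(1.0, k_bm)
        assert k_shuf.p_value > 0.05


class TestPagelLambda:
    @pytest.mark.parametrize("lam", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_profile_likelihood_matches_reference(self, fixture_tree, lam):
        from rootallometry.phylo import _profile_loglik, _trait_vector

        C, labels = vcv_matrix(fixture_tree)
        z = _trait_vector(FIXTURE_X, labels)
        assert _profile_loglik(z, C, lam) == pytest.approx(
            REF_LAMBDA_LOGLIK[lam], abs=1e-8
        )

    def test_fixture_ml_on_upper_bound(self, fixture_tree):
        # the unconstrained ML sits above 1; on [0, 1] the optimum is 1
        res = pagel_lambda_ml(fixture_tree, FIXTURE_X)
        assert res.estimate == pytest.approx(1.0, abs=1e-5)
        assert res.detail["log_likelihood"] == pytest.approx(
            REF_LAMBDA_LOGLIK[1.0], abs=1e-8
        )

    def test_ml_beats_grid(self):
        tree = simulate_tree(60, seed=8)
        z = simulate_bm_trait(tree, 1.0, lam=0.6, seed=9)
        from rootallometry.phylo import _profile_loglik, _trait_vector

        C, labels = vcv_matrix(tree)
        vec = _trait_vector(z, labels)
        res = pagel_lambda_ml(tree, z)
        grid = [_profile_loglik(vec, C, g) for g in np.linspace(0, 1, 51)]
        assert res.detail["log_likelihood"] >= max(grid) - 1e-7

    def test_star_tree_unidentifiable(self):
        star = read_newick("(a:1,b:1,c:1,d:1);")
        with pytest.raises(PhyloError, match="star"):
            pagel_lambda_ml(star, {"a": 1, "b": 2, "c": 3, "d": 4})


class TestPGLS:
    def test_matches_reference_fit(self, fixture_tree):
        res = pgls(
            fixture_tree,
            FIXTURE_Y,
            pd.DataFrame({"x": pd.Series(FIXTURE_X)}),
            correlation="bm",
        )
        assert res.params["intercept"] == pytest.approx(REF_PGLS_INTERCEPT, abs=1e-8)
        assert res.params["x"] == pytest.approx(REF_PGLS_SLOPE, abs=1e-8)
        assert res.se["intercept"] == pytest.approx(REF_PGLS_SE[0], abs=1e-7)
        assert res.se["x"] == pytest.approx(REF_PGLS_SE[1], abs=1e-7)

    def test_exact_linear_response(self, fixture_tree):
        x = pd.Series(FIXTURE_X)
        y = 3.0 * x - 1.0
        res = pgls(fixture_tree, y, pd.DataFrame({"x": x}))
        assert res.params["x"] == pytest.approx(3.0)
        assert res.params["intercept"] == pytest.approx(-1.0)
        assert res.sigma2 == pytest.approx(0.0, abs=1e-12)

    def test_rank_deficiency_names_columns(self, fixture_tree):
        x = pd.Series(FIXTURE_X)
        X = pd.DataFrame({"x": x, "x_copy": 2 * x})
        with pytest.raises(ValueError, match="x_copy"):
            pgls(fixture_tree, FIXTURE_Y, X)

    def test_interaction_design_runs(self, fixture_tree):
        x = pd.Series(FIXTURE_X)
        grp = pd.Series([1.0] * 5 + [0.0] * 5, index=x.index)
        X = pd.DataFrame({"x": x, "g": grp, "x_g": x * grp})
        res = pgls(fixture_tree, FIXTURE_Y, X)
        assert set(res.params.index) == {"intercept", "x", "g", "x_g"}


@pytest.fixture(scope="module")
def setup():
    tree = simulate_tree(40, seed=21)
    x = simulate_bm_trait(tree, 1.0, seed=22)
    y = simulate_bm_trait(tree, 1.0, lam=0.7, seed=23)
    return tree, x, y


class TestInvariances:
    """K, lambda, PIC correlation and PGLS slope are invariant to tip
    relabelling order and to uniform branch-length rescaling."""

    def test_branch_rescaling(self, setup):
        tree, x, y = setup
        scaled = read_newick(write_newick(tree))
        for edge in scaled.edges():
            if edge.length is not None:
                edge.length *= 7.5
        assert blomberg_k(tree, x, n_permutations=0).estimate == pytest.approx(
            blomberg_k(scaled, x, n_permutations=0).estimate, rel=1e-8
        )
        assert pagel_lambda_ml(tree, y).estimate == pytest.approx(
            pagel_lambda_ml(scaled, y).estimate, abs=1e-4
        )
        assert pic_regression(tree, x, y).r == pytest.approx(
            pic_regression(scaled, x, y).r, rel=1e-10
        )

    def test_trait_order_irrelevant(self, setup):
        tree, x, y = setup
        shuffled = x.sample(frac=1.0, random_state=0)
        assert blomberg_k(tree, shuffled, n_permutations=0).estimate == (
            pytest.approx(blomberg_k(tree, x, n_permutations=0).estimate)
        )


class TestReconcile:
    def test_underscore_and_space_equivalence(self):
        tree = read_newick("((Abies_alba:1,Pinus_mugo:1):1,Quercus_robur:2);")
        mapping, unmatched = reconcile_species(
            ["Abies alba", " Pinus_mugo ", "Fagus sylvatica"], tree
        )
        assert mapping["Abies alba"] == "Abies_alba"
        assert mapping[" Pinus_mugo "] == "Pinus_mugo"
        assert set(mapping.values()) <= set(tip_labels(tree))
        assert unmatched == ["Fagus sylvatica"]
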