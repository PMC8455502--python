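import math

import numpy as np
import pytest

from hgtsignal.phylo_core import (
    PhyloTree,
    TreeError,
    fit_rate,
    marginal_ancestral,
    mk_transition_matrix,
    parse_newick,
    prune_log_likelihood,
    write_newick,
)
from hgtsignal.synthetic_data import (
    brute_force_likelihood,
    brute_force_marginals,
    random_tree,
    simulate_mk_trait,
    simulate_yule,
)


def tree_signature(tree: PhyloTree):
    """Topology + lengths + supports as a comparable set of clades."""
    sig = set()
    for node in tree.postorder():
        tips = frozenset(
            n.label for n in PhyloTree(node, validate=False).postorder() if n.is_tip
        )
        # lengths survive to printed precision (10 significant digits);
        # compare a little coarser to dodge re-parse rounding at the ulp
        length = None if node.parent is None else round(node.length, 6)
        sig.add((tips, length, node.support))
    return sig


class TestNewick:
    def test_minimal_tree(self):
        t = parse_newick("(A:1.0,B:2.0);")
        assert sorted(t.tip_labels()) == ["A", "B"]
        assert len(t.root.children) == 2

    def test_support_as_internal_label(self):
        t = parse_newick("((A:1,B:1)95:0.5,C:2);")
        inner = t.root.children[0]
        assert inner.support == 95
        assert inner.length == 0.5

    @pytest.mark.parametrize(
        "bad",
        ["((A:1,A:2),B:1);", "((A:1,B:1,C:2);", "(A:-1.0,B:2.0);"],
        ids=["duplicate-tip", "unbalanced", "negative-length"],
    )
    def test_malformed_rejected(self, bad):
        with pytest.raises(TreeError):
            parse_newick(bad)

    def test_round_trip_minimal(self):
        t = parse_newick("(A:1.0,B:2.0);")
        assert write_newick(t) == "(A:1,B:2);"

    def test_round_trip_preserves_structure(self):
        for seed in range(10):
            t = random_tree(8, seed=seed)
            back = parse_newick(write_newick(t))
            assert tree_signature(back) == tree_signature(t)

    def test_polytomy_and_support_round_trip(self):
        text = "((A:1,B:1,C:1)80:0.5,(D:1,E:1)60:0.25,F:2);"
        t = parse_newick(text)
        assert len(t.root.children) == 3
        back = parse_newick(write_newick(t))
        assert tree_signature(back) == tree_signature(t)

    def test_quoted_label_with_space(self):
        t = parse_newick("(('Aus x':1,B:1):0.5,C:2);")
        assert "Aus x" in t.tip_labels()
        assert "Aus x" in parse_newick(write_newick(t)).tip_labels()


class TestTransitionMatrix:
    def test_zero_time_is_identity(self):
        assert np.allclose(mk_transition_matrix(1.0, 0.0, 3), np.eye(3))

    def test_stationary_limit(self):
        P = mk_transition_matrix(5.0, 1e6, 4)
        assert np.allclose(P, 0.25)

    def test_closed_form_value(self):
        P = mk_transition_matrix(1.0, 0.5, 2)
        assert P[0, 0] == pytest.approx(0.5 + 0.5 * math.exp(-1), abs=1e-12)

    def test_rows_sum_to_one_randomized(self, rng):
        for _ in range(1000):
            r = rng.uniform(0, 10)
            t = rng.uniform(0, 5)
            k = int(rng.integers(2, 8))
            P = mk_transition_matrix(r, t, k)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
            assert np.allclose(P, P.T)
            assert P.min() >= 0 and P.max() <= 1

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            mk_transition_matrix(float("nan"), 1.0, 2)
        with pytest.raises(ValueError):
            mk_transition_matrix(-1.0, 1.0, 2)


class TestPruning:
    def test_zero_length_branches_act_as_identity(self):
        # two zero-length same-state tips collapse onto their parent, so the
        # likelihood reduces to that of the remaining informative branch
        t = parse_newick("((A:0,B:0):0,C:1);")
        traits = {"A": "Plant", "B": "Plant", "C": "Soil"}
        ll = prune_log_likelihood(t, traits, 0.7)
        assert ll == pytest.approx(
            brute_force_likelihood(t, traits, 0.7), abs=1e-9
        )
        # identical to a 2-tip tree with the cherry fused into one tip
        t2 = parse_newick("(A:0,C:1);")
        assert ll == pytest.approx(
            prune_log_likelihood(t2, {"A": "Plant", "C": "Soil"}, 0.7), abs=1e-9
        )

    def test_infinite_rate_independence_limit(self):
        t = random_tree(5, seed=3)
        traits = simulate_mk_trait(t, 3, rate=1.0, seed=4)
        if len(set(traits.values())) < 2:
            traits[t.tip_labels()[0]] = "Plant"
        k = len(set(traits.values()))
        n = t.n_tips
        assert prune_log_likelihood(t, traits, 1e6) == pytest.approx(
            n * math.log(1 / k), rel=1e-6
        )

    def test_matches_enumeration_on_random_trees(self, rng):
        checked = 0
        seed = 0
        while checked < 50:
            seed += 1
            n = int(rng.integers(3, 7))
            k = int(rng.integers(2, 5))
            tree = random_tree(n, seed=seed)
            traits = simulate_mk_trait(tree, k, rate=1.0, seed=1000 + seed)
            if len(set(traits.values())) < 2:
                continue
            r = float(rng.uniform(0.05, 3.0))
            assert prune_log_likelihood(tree, traits, r) == pytest.approx(
                brute_force_likelihood(tree, traits, r), abs=1e-9
            )
            checked += 1

    def test_invariant_under_child_reordering(self):
        tree = random_tree(6, seed=11)
        traits = simulate_mk_trait(tree, 3, rate=0.8, seed=12)
        if len(set(traits.values())) < 2:
            traits[tree.tip_labels()[0]] = "Soil"
        before = prune_log_likelihood(tree, traits, 0.6)
        for node in tree.postorder():
            node.children.reverse()
        assert prune_log_likelihood(tree, traits, 0.6) == pytest.approx(
            before, abs=1e-12
        )

    def test_errors(self):
        t = parse_newick("(A:1,B:1);")
        with pytest.raises(TreeError):
            prune_log_likelihood(t, {"A": "Plant"}, 1.0)
        with pytest.raises(ValueError):
            prune_log_likelihood(t, {"A": "Plant", "B": "Soil"}, -1.0)


class TestFitRate:
    def test_clustered_trait_gives_small_rate(self):
        # two clades separated by a long branch, perfectly sorted trait
        t = parse_newick(
            "((A:0.1,B:0.1):5.0,(C:0.1,D:0.1):5.0);"
        )
        traits = {"A": "Plant", "B": "Plant", "C": "Soil", "D": "Soil"}
        r = fit_rate(t, traits)
        ll = prune_log_likelihood(t, traits, r)
        assert ll >= prune_log_likelihood(t, traits, 10 * r)

    def test_random_trait_gives_large_rate(self):
        tree = simulate_yule(30, seed=21)
        rng = np.random.default_rng(22)
        cats = ["Plant", "Soil", "Aquatic"]
        traits = {l: cats[rng.integers(3)] for l in tree.tip_labels()}
        r = fit_rate(tree, traits)
        assert r >= 1.0

    def test_constant_trait_is_an_error(self):
        t = parse_newick("(A:1,(B:1,C:1):1);")
        with pytest.raises(TreeError, match="undefined"):
            fit_rate(t, {"A": "Plant", "B": "Plant", "C": "Plant"})


class TestMarginalAncestral:
    def test_certain_when_all_tips_agree_at_zero_length(self):
        t = parse_newick("((A:0,B:0):0,(C:0,D:1):0);")
        traits = {"A": "Plant", "B": "Plant", "C": "Plant", "D": "Soil"}
        anc = marginal_ancestral(t, traits, 1e-8)
        for vec in anc.values():
            assert vec.sum() == pytest.approx(1.0, abs=1e-12)
        # near-zero rate and zero lengths: internal nodes follow their tips
        first_cherry = min(anc)  # postorder: first internal node is (A,B)
        assert anc[first_cherry][0] == pytest.approx(1.0, abs=1e-6)

    def test_matches_enumeration_balanced_four_tips(self):
        t = parse_newick("((A:1,B:1):0.5,(C:1,D:1):0.5);")
        traits = {"A": "Plant", "B": "Plant", "C": "Soil", "D": "Soil"}
        anc = marginal_ancestral(t, traits, 0.5)
        oracle = brute_force_marginals(t, traits, 0.5)
        assert set(anc) == set(oracle)
        for key in anc:
            assert np.allclose(anc[key], oracle[key], atol=1e-9)

    def test_root_uniform_in_stationary_limit(self):
        t = parse_newick("(A:1000,B:1000);")
        anc = marginal_ancestral(t, {"A": "Plant", "B": "Soil"}, 1.0)
        (vec,) = anc.values()
        assert np.allclose(vec, 0.5, atol=1e-6)

    def test_matches_enumeration_randomized(self, rng):
        checked = 0
        seed = 100
        while checked < 20:
            seed += 1
            tree = random_tree(int(rng.integers(4, 7)), seed=seed)
            traits = simulate_mk_trait(tree, 3, rate=1.2, seed=seed + 1)
            if len(set(traits.values())) < 2:
                continue
            r = float(rng.uniform(0.1, 2.0))
            anc = marginal_ancestral(tree, traits, r)
            oracle = brute_force_marginals(tree, traits, r)
            for key in oracle:
                assert np.allclose(anc[key], oracle[key], atol=1e-9)
            checked += 1
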