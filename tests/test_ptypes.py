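import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from microconnectome import ptypes as pt


def chain_tree():
    """S - R - N - {T1, T2} chain with the probabilities of the worked
    example: S->R 0.8, R->N 0.5, N->T1 0.4, N->T2 0.3."""
    tree = pt.PTypeTree(
        leaves=["S", "T1", "T2"],
        children={"R": ["S", "N"], "N": ["T1", "T2"]},
        root="R")
    tree.set_probability("S", "R", 0.8)
    tree.set_probability("R", "N", 0.5)
    tree.set_probability("N", "T1", 0.4)
    tree.set_probability("N", "T2", 0.3)
    return tree


class TestInnervationProbability:
    def test_l23_constant(self):
        assert pt.innervation_probability(0.04, "L23") == pytest.approx(0.1)

    def test_zero_nps(self):
        assert pt.innervation_probability(0.0, "L5PT") == 0.0

    def test_clipped_at_one(self):
        assert pt.innervation_probability(100.0, "L5IT") == 1.0

    def test_unknown_class_raises(self):
        with pytest.raises(ValueError):
            pt.innervation_probability(0.1, "L7")


class TestPathProbability:
    def test_shared_parent_product(self):
        tree = pt.PTypeTree(leaves=["A", "B"], children={"r": ["A", "B"]},
                            root="r")
        tree.set_probability("A", "r", 0.5)
        tree.set_probability("r", "B", 0.5)
        assert pt.path_probability(tree, "A", "B") == pytest.approx(0.25)

    def test_chain_product_oracle(self):
        tree = chain_tree()
        assert pt.path_probability(tree, "S", "T1") == pytest.approx(
            0.8 * 0.5 * 0.4)

    def test_same_region_raises(self):
        tree = chain_tree()
        with pytest.raises(ValueError):
            pt.path_probability(tree, "S", "S")

    def test_epsilon_edge_bounds_probability(self):
        tree = chain_tree()
        tree.set_probability("S", "R", pt.EPSILON)
        assert pt.path_probability(tree, "S", "T1") <= pt.EPSILON


class TestConditionalIncrease:
    def test_worked_example(self):
        tree = chain_tree()
        inc = pt.conditional_increase(tree, "S", "T1", "T2")
        assert inc == pytest.approx(1.0 / (0.8 * 0.5))
        # cross-check: P(T1|T2) = 2.5 x P(T1)
        p1 = pt.path_probability(tree, "S", "T1")
        assert inc * p1 == pytest.approx(0.4)

    def test_unit_probabilities_give_independence(self):
        tree = chain_tree()
        tree.set_probability("S", "R", 1.0)
        tree.set_probability("R", "N", 1.0)
        assert pt.conditional_increase(tree, "S", "T1", "T2") == 1.0

    def test_symmetric_in_targets(self):
        for seed in range(5):
            tree = pt.random_tree(8, seed=seed)
            for t1, t2 in itertools.combinations(tree.leaves[1:], 2):
                a = pt.conditional_increase(tree, "R1", t1, t2)
                b = pt.conditional_increase(tree, "R1", t2, t1)
                assert a == pytest.approx(b, abs=1e-12)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_always_at_least_one(self, seed):
        r = np.random.default_rng(seed)
        tree = pt.random_tree(int(r.integers(3, 10)), seed=seed)
        s, t1, t2 = r.choice(tree.leaves, size=3, replace=False)
        assert pt.conditional_increase(tree, s, t1, t2) >= 1.0 - 1e-12

    def test_requires_distinct_leaves(self):
        tree = chain_tree()
        with pytest.raises(ValueError):
            pt.conditional_increase(tree, "S", "T1", "T1")


class TestClosedFormsAgainstEnumeration:
    @pytest.mark.parametrize("n_leaves,seed", [(3, 0), (4, 1), (5, 2),
                                               (6, 3), (7, 4)])
    def test_marginals_and_conditionals_exact(self, n_leaves, seed):
        tree = pt.random_tree(n_leaves, seed=seed)
        assert len(tree.parent) * 1 <= 12  # <= 12 undirected edges
        source = tree.leaves[0]
        dist = pt.enumerate_profile_distribution(tree, source)
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)
        for tgt in tree.leaves[1:]:
            p_enum = sum(w for prof, w in dist.items() if tgt in prof)
            assert p_enum == pytest.approx(
                pt.path_probability(tree, source, tgt), abs=1e-12)
        for t1, t2 in itertools.combinations(tree.leaves[1:], 2):
            p1 = sum(w for prof, w in dist.items() if t1 in prof)
            p12 = sum(w for prof, w in dist.items()
                      if t1 in prof and t2 in prof)
            p2 = sum(w for prof, w in dist.items() if t2 in prof)
            inc_enum = (p12 / p2) / p1
            assert inc_enum == pytest.approx(
                pt.conditional_increase(tree, source, t1, t2), abs=1e-9)


class TestBuildTreeTopology:
    def test_two_regions_make_a_cherry(self):
        ncd = pd.DataFrame([[0, 1.0], [1.0, 0]], index=["a", "b"],
                           columns=["a", "b"])
        tree = pt.build_tree_topology(ncd, seed=0)
        assert sorted(tree.children[tree.root]) == ["a", "b"]

    def test_two_blocks_merge_before_root(self):
        regs = ["a1", "a2", "b1", "b2"]
        m = np.full((4, 4), 0.01)
        m[0, 1] = m[1, 0] = m[2, 3] = m[3, 2] = 5.0
        np.fill_diagonal(m, 0)
        ncd = pd.DataFrame(m, index=regs, columns=regs)
        tree = pt.build_tree_topology(ncd, seed=0)
        # the two dense pairs become sibling inner nodes below the root
        kids = tree.children[tree.root]
        leafsets = []
        for k in kids:
            stack, leaves = [k], set()
            while stack:
                n = stack.pop()
                if n in tree.children:
                    stack.extend(tree.children[n])
                else:
                    leaves.add(n)
            leafsets.append(leaves)
        assert {frozenset(s) for s in leafsets} == {
            frozenset({"a1", "a2"}), frozenset({"b1", "b2"})}

    def test_deterministic_given_seed(self, rng):
        n = 7
        regs = [f"r{i}" for i in range(n)]
        m = rng.random((n, n))
        ncd = pd.DataFrame(m, index=regs, columns=regs)
        t1 = pt.build_tree_topology(ncd, seed=42)
        t2 = pt.build_tree_topology(ncd, seed=42)
        assert t1.children == t2.children

    def test_empty_matrix_raises(self):
        with pytest.raises(ValueError):
            pt.build_tree_topology(pd.DataFrame())


class TestFitEdgeProbabilities:
    def test_forward_generate_then_refit_recovers_paths(self):
        for seed in range(5):
            tree = pt.random_tree(10, seed=seed)
            m = pt.pathlength_matrix(tree)
            skel = pt.PTypeTree(leaves=tree.leaves,
                                children=dict(tree.children), root=tree.root)
            fitted = pt.fit_edge_probabilities(skel, m)
            m2 = pt.pathlength_matrix(fitted)
            assert np.abs(m.values - m2.values).max() < 1e-6
            assert all(v >= 0 for v in fitted.lengths.values())

    def test_symmetric_star_gives_equal_motif_weights(self):
        skel = pt.PTypeTree(leaves=["a", "b"], children={"r": ["a", "b"]},
                            root="r")
        m = pd.DataFrame([[0, 0.6], [0.6, 0]], index=["a", "b"],
                         columns=["a", "b"])
        fitted = pt.fit_edge_probabilities(skel, m)
        vals = [fitted.lengths[("a", "r")], fitted.lengths[("b", "r")],
                fitted.lengths[("r", "a")], fitted.lengths[("r", "b")]]
        assert np.allclose(vals, vals[0])

    def test_three_leaf_least_squares_matches_normal_equations(self):
        tree = pt.random_tree(3, seed=9)
        m = pt.pathlength_matrix(tree)
        skel = pt.PTypeTree(leaves=tree.leaves, children=dict(tree.children),
                            root=tree.root)
        fitted = pt.fit_edge_probabilities(skel, m)
        # independent oracle: solve the first motif system via normal
        # equations and compare the gauge-invariant combinations
        inner = [n for n in skel.children if
                 all(c not in skel.children for c in skel.children[n])][0]
        t1, t2 = skel.children[inner]
        refs = [x for x in tree.leaves if x not in (t1, t2)]
        A = np.array([[1, -1, 0, 0], [0, 0, 1, -1], [1, 0, 0, 1],
                      [0, 1, 1, 0]], dtype=float)
        b = np.array([
            np.mean([m.loc[t1, x] - m.loc[t2, x] for x in refs]),
            np.mean([m.loc[x, t1] - m.loc[x, t2] for x in refs]),
            m.loc[t1, t2], m.loc[t2, t1]])
        sol = np.linalg.solve(A.T @ A + 1e-12 * np.eye(4), A.T @ b)
        got = np.array([fitted.lengths[(t1, inner)],
                        fitted.lengths[(t2, inner)],
                        fitted.lengths[(inner, t1)],
                        fitted.lengths[(inner, t2)]])
        # gauge-invariant: differences and cross sums
        assert got[0] - got[1] == pytest.approx(sol[0] - sol[1], abs=1e-8)
        assert got[2] - got[3] == pytest.approx(sol[2] - sol[3], abs=1e-8)
        assert got[0] + got[3] == pytest.approx(sol[0] + sol[3], abs=1e-8)

    def test_missing_entries_replaced_by_epsilon_length(self):
        skel = pt.PTypeTree(leaves=["a", "b"], children={"r": ["a", "b"]},
                            root="r")
        m = pd.DataFrame([[0, np.inf], [0.3, 0]], index=["a", "b"],
                         columns=["a", "b"])
        fitted = pt.fit_edge_probabilities(skel, m)
        assert fitted.path_length("a", "b") <= -np.log10(pt.EPSILON) + 1e-9


class TestSampling:
    def test_all_unit_probabilities_innervate_everything(self):
        tree = pt.random_tree(6, seed=0)
        for k in list(tree.lengths):
            tree.lengths[k] = 0.0
        mat = pt.sample_innervation_profiles(tree, "R2", 10, seed=0)
        assert (mat.drop(columns=["R2"]) == 1).all().all()
        assert (mat["R2"] == 0).all()  # source column fixed at 0

    def test_blocked_source_edge_gives_empty_profiles(self):
        tree = pt.random_tree(6, seed=0)
        tree.lengths[("R3", tree.parent["R3"])] = np.inf
        mat = pt.sample_innervation_profiles(tree, "R3", 25, seed=0)
        assert (mat == 0).all().all()

    def test_deterministic_per_seed(self):
        tree = pt.random_tree(6, seed=1)
        a = pt.sample_innervation_profiles(tree, "R1", 100, seed=5)
        b = pt.sample_innervation_profiles(tree, "R1", 100, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_monte_carlo_matches_closed_forms(self):
        tree = chain_tree()
        n = 10_000
        mat = pt.sample_innervation_profiles(tree, "S", n, seed=0)
        for tgt in ("T1", "T2"):
            p = pt.path_probability(tree, "S", tgt)
            se = np.sqrt(p * (1 - p) / n)
            assert abs(mat[tgt].mean() - p) < 3 * se
        # conditional increase T1 | T2
        sel = mat[mat["T2"] == 1]
        p_cond = sel["T1"].mean()
        p1 = pt.path_probability(tree, "S", "T1")
        expect = pt.conditional_increase(tree, "S", "T1", "T2") * p1
        se = np.sqrt(expect * (1 - expect) / len(sel))
        assert abs(p_cond - expect) < 3 * se


class TestPairwiseIndependence:
    def test_full_overlap_rejected(self):
        mat = pd.DataFrame({"a": [1] * 10 + [0] * 10,
                            "b": [1] * 10 + [0] * 10})
        out = pt.test_pairwise_independence(mat, "a", "b")
        from scipy.special import comb
        assert out["p_value"] == pytest.approx(2 / comb(20, 10), rel=1e-9)
        assert out["reject"] and out["increase"] == pytest.approx(2.0)

    def test_overlap_at_expectation_not_rejected(self):
        # N=20, n_a=10, n_b=10, overlap 5 = expectation
        a = [1] * 10 + [0] * 10
        b = [1] * 5 + [0] * 5 + [1] * 5 + [0] * 5
        out = pt.test_pairwise_independence(pd.DataFrame({"a": a, "b": b}),
                                            "a", "b")
        assert not out["reject"]
        assert out["increase"] == pytest.approx(1.0)

    def test_empty_column_flagged(self):
        mat = pd.DataFrame({"a": [0, 0, 0], "b": [1, 0, 1]})
        out = pt.test_pairwise_independence(mat, "a", "b")
        assert out["p_value"] == 1.0 and out["flagged"] and not out["reject"]


class TestHammingDistributions:
    def test_identical_sets_ks_zero(self):
        tree = pt.random_tree(8, seed=0)
        mat = pt.sample_innervation_profiles(tree, "R1", 50, seed=1)
        out = pt.compare_hamming_distributions(mat, mat.copy())
        assert out["ks_statistic"] == 0.0

    def test_tree_model_wider_than_naive_control(self):
        # strong shared-path correlations widen the distance distribution
        tree = chain_tree()
        n = 10_000
        model = pt.sample_innervation_profiles(tree, "S", n, seed=2)
        model = model.drop(columns=["S"])
        probs = pd.Series({t: pt.path_probability(tree, "S", t)
                           for t in model.columns})
        naive = pt.sample_naive_profiles(probs, n, seed=3)
        out = pt.compare_hamming_distributions(model, naive)
        assert out["distances_a"].var() > out["distances_b"].var()

    def test_too_few_profiles_raise(self):
        df = pd.DataFrame({"a": [1]})
        with pytest.raises(ValueError):
            pt.compare_hamming_distributions(df, df)


class TestCombinatorics:
    def test_profile_space_of_27_targets(self):
        assert pt.num_possible_ptypes(27) == 134_217_728

    def test_pair_count_of_86_regions(self):
        assert pt.num_region_pairs(86) == 3_655


class TestSerialization:
    def test_json_round_trip(self):
        tree = pt.random_tree(5, seed=4)
        back = pt.PTypeTree.from_json(tree.to_json())
        assert back.leaves == tree.leaves
        assert set(back.lengths) == {(str(u), str(v)) for u, v in tree.lengths}

    def test_newick_contains_all_leaves(self):
        tree = pt.random_tree(5, seed=4)
        nwk = tree.to_newick()
        assert nwk.endswith(";")
        for leaf in tree.leaves:
            assert leaf in nwk
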