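import numpy as np
import pytest

import microcensus as mc
from microcensus.core import AbundanceTable, Experiment
from microcensus.distances import (
    DistanceMatrix,
    branch_abundance,
    distance,
    list_distance_methods,
    unifrac,
)

# ---------------------------------------------------------------------------
# Reference values: r-vegan 2.7 vegdist/betadiver on this exact matrix
# (4 samples x 5 taxa), pair order (s0,s1),(s0,s2),(s0,s3),(s1,s2),(s1,s3),(s2,s3)
# ---------------------------------------------------------------------------
X = np.array([[1, 0, 3, 5, 2],
              [2, 1, 1, 0, 4],
              [0, 0, 7, 2, 1],
              [3, 3, 0, 1, 0]], dtype=float)

VEGAN = {
    "manhattan": [11, 9, 14, 14, 9, 15],
    "euclidean": [5.91607978310, 5.19615242271, 6.48074069841,
                  7.34846922835, 4.79583152331, 8.30662386292],
    "canberra": [0.633333333333, 0.540476190476, 0.833333333333,
                 0.870000000000, 0.740000000000, 0.866666666667],
    "bray": [0.578947368421, 0.428571428571, 0.777777777778,
             0.777777777778, 0.600000000000, 0.882352941176],
    "kulczynski": [0.568181818182, 0.427272727273, 0.766233766234,
                   0.775000000000, 0.598214285714, 0.878571428571],
    "jaccard": [0.733333333333, 0.600000000000, 0.875, 0.875, 0.75, 0.9375],
    "gower": [0.490476190476, 0.350952380952, 0.679047619048,
              0.601428571429, 0.468571428571, 0.690000000000],
    "altGower": [2.20, 2.25, 2.80, 2.80, 1.80, 3.00],
    "morisita": [0.414414414414, 0.192934782609, 0.615384615385,
                 0.627819548872, 0.400000000000, 0.926229508197],
    "horn": [0.556417215975, 0.304197814836, 0.707363420428,
             0.688826025460, 0.560592850915, 0.938407391113],
    "mountford": [0.036891201323, 0.0, 0.310902094720,
                  0.310902094720, 0.310902094720, 0.528714533698],
    "raup": [1.0, 0.4, 1.0, 1.0, 1.0, 1.0],
    "binomial": [1.630372421591, 0.926940663305, 2.452839549315,
                 2.588563318005, 2.230389091172, 2.829221734505],
    "chao": [0.34026832587984, 0.00909090909091, 0.39612138624529,
             0.15, 0.625, 0.89473684210526],
    "cao": [1.084944099531, 0.556073231059, 1.743967208615,
            1.538990461116, 1.280149636477, 2.088356183330],
    "chisq": [1.346966811222, 0.986438035486, 1.785431983696,
              1.612615142370, 1.565060517955, 2.103535322602],
    "w": [0.25, 0.142857142857, 0.428571428571, 0.428571428571,
          0.428571428571, 0.666666666667],
    "-1": [0.25, 0.142857142857, 0.428571428571, 0.428571428571,
           0.428571428571, 0.666666666667],
    "c": [1.0, 0.5, 1.5, 1.5, 1.5, 2.0],
    "wb": [2, 1, 3, 3, 3, 4],
    "r": [0.0869565217391, 0.0, 0.1904761904762, 0.1904761904762,
          0.1904761904762, 0.4705882352941],
    "I": [0.1732867951400, 0.0887819499348, 0.2868240015234,
          0.2868240015234, 0.2868240015234, 0.4620981203733],
    "e": [0.1892071150027, 0.0928423360018, 0.3321897294789,
          0.3321897294789, 0.3321897294789, 0.5874010519682],
    "t": [0.25, 0.142857142857, 0.428571428571, 0.428571428571,
          0.428571428571, 0.666666666667],
    "me": [0.25, 0.142857142857, 0.428571428571, 0.428571428571,
           0.428571428571, 0.666666666667],
    "j": [0.60, 0.75, 0.40, 0.40, 0.40, 0.20],
    "sor": [0.75, 0.857142857143, 0.571428571429, 0.571428571429,
            0.571428571429, 0.333333333333],
    "m": [3.20, 1.75, 4.20, 4.20, 4.20, 4.80],
    "-2": [0.25, 0.0, 0.25, 0.25, 0.25, 0.666666666667],
    "co": [0.25, 0.125, 0.416666666667, 0.416666666667,
           0.416666666667, 0.666666666667],
    "cc": [0.40, 0.25, 0.60, 0.60, 0.60, 0.80],
    "g": [0.40, 0.25, 0.60, 0.60, 0.60, 0.80],
    "-3": [0.2, 0.0, 0.2, 0.2, 0.2, 0.4],
    "l": [1.0, 0.5, 1.5, 1.5, 1.5, 2.0],
    "19": [0.2, 0.166666666667, 0.3, 0.3, 0.3, 0.5],
    "hk": [0.25, 0.142857142857, 0.428571428571, 0.428571428571,
           0.428571428571, 0.666666666667],
    "rlb": [0.75, 0.75, 0.5, 0.5, 0.5, 0.333333333333],
    "sim": [0.25, 0.0, 0.333333333333, 0.333333333333,
            0.333333333333, 0.666666666667],
    "gl": [0.0, 0.285714285714, 0.285714285714, 0.285714285714,
           0.285714285714, 0.0],
    "z": [0.321928094887, 0.192645077942, 0.514573172830,
          0.514573172830, 0.514573172830, 0.736965594166],
}
PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


@pytest.fixture(scope="module")
def vegan_exp():
    ab = AbundanceTable(X.T, [f"t{i}" for i in range(5)],
                        [f"s{i}" for i in range(4)])
    return Experiment(ab)


class TestRegistry:
    def test_more_than_40_distinct_methods(self):
        methods = list_distance_methods()
        assert len(methods) > 40
        assert len(set(methods)) == len(methods)
        for name in ("unifrac", "wunifrac", "bray", "jaccard", "jsd"):
            assert name in methods

    def test_unknown_method_lists_registry(self, vegan_exp):
        with pytest.raises(ValueError, match="bray"):
            distance(vegan_exp, "nosuchmethod")

    def test_tree_method_without_tree(self, vegan_exp):
        with pytest.raises(ValueError, match="tree"):
            distance(vegan_exp, "unifrac")

    @pytest.mark.parametrize("method", sorted(VEGAN))
    def test_matches_independent_reference(self, vegan_exp, method):
        d = distance(vegan_exp, method)
        got = [d.values[i, j] for i, j in PAIRS]
        np.testing.assert_allclose(got, VEGAN[method], atol=1e-9)

    def test_hand_examples(self, vegan_exp):
        # bray on (1,0,3) vs (2,1,1): |diff|=4 over sum=8
        ab = AbundanceTable(np.array([[1, 2], [0, 1], [3, 1]], float),
                            ["a", "b", "c"], ["x", "y"])
        e = Experiment(ab)
        assert distance(e, "bray").values[0, 1] == pytest.approx(0.5)
        ab2 = AbundanceTable(np.array([[0, 3], [0, 4]], float) + [[1], [1]],
                            ["a", "b"], ["x", "y"])
        # euclidean on (0,0) vs (3,4) shifted by 1 stays 5
        assert distance(Experiment(ab2), "euclidean").values[0, 1] == pytest.approx(5)

    def test_jaccard_identical_presence_is_zero(self):
        ab = AbundanceTable(np.array([[1, 2], [3, 1], [0, 0]], float),
                            ["a", "b", "c"], ["x", "y"])
        d = distance(Experiment(ab), "jaccard", binary=True)
        assert d.values[0, 1] == 0

    def test_symmetry_zero_diag_nonnegative_all_methods(self, grouped_exp):
        sub = mc.prune_samples(grouped_exp.sample_ids[:4], grouped_exp)
        for method in list_distance_methods():
            d = distance(sub, method)
            assert np.allclose(d.values, d.values.T)
            assert np.all(np.diag(d.values) == 0)
            assert np.all(d.values >= 0), method

    def test_euclidean_triangle_inequality(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            ab = AbundanceTable(rng.integers(0, 9, (6, 5)).astype(float) + 1,
                                [f"t{i}" for i in range(6)],
                                [f"s{i}" for i in range(5)])
            d = distance(Experiment(ab), "euclidean").values
            n = d.shape[0]
            for i in range(n):
                for j in range(n):
                    for k in range(n):
                        assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    def test_zero_total_sample_is_error(self):
        ab = AbundanceTable(np.array([[1, 0], [1, 0]], float), ["a", "b"], ["x", "y"])
        with pytest.raises(ValueError, match="y"):
            distance(Experiment(ab), "bray")

    def test_jsd_closed_form(self):
        # P=(1,0), Q=(0,1): JSD = log 2
        ab = AbundanceTable(np.array([[1, 0], [0, 1]], float), ["a", "b"], ["x", "y"])
        assert distance(Experiment(ab), "jsd").values[0, 1] == pytest.approx(np.log(2))


# ---------------------------------------------------------------------------
# UniFrac
# ---------------------------------------------------------------------------

def brute_force_unifrac(exp, i, j, weighted, normalized):
    """Independent oracle: explicit edge enumeration with per-edge leaf sets,
    no shared precompute."""
    tree = exp.tree._tree
    frame = exp.abundance.to_frame()
    si, sj = exp.sample_ids[i], exp.sample_ids[j]
    AT, BT = frame[si].sum(), frame[sj].sum()
    num = den = raw = 0.0
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        b = node.edge.length or 0.0
        tips = [leaf.taxon.label for leaf in node.leaf_iter()]
        A = sum(frame.loc[t, si] for t in tips)
        B = sum(frame.loc[t, sj] for t in tips)
        if (A > 0) != (B > 0):
            num += b
        if A > 0 or B > 0:
            den += b
        raw += b * abs(A / AT - B / BT)
    if not weighted:
        return num / den if den else 0.0
    if not normalized:
        return raw
    D = sum(leaf.distance_from_root()
            * (frame.loc[leaf.taxon.label, si] / AT
               + frame.loc[leaf.taxon.label, sj] / BT)
            for leaf in tree.leaf_node_iter())
    return raw / D if D else 0.0


def random_experiment_with_tree(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 9))
    tree = mc.random_tree(n, seed=seed + 1000)
    counts = rng.integers(0, 5, size=(n, 3)).astype(float)
    counts[rng.integers(0, n), counts.sum(axis=0) == 0] = 1
    ab = AbundanceTable(counts, tree.tip_labels, ["A", "B", "C"])
    return mc.build_experiment(ab, tree=tree)


class TestUniFrac:
    def test_branch_abundance_cherry(self):
        tree = mc.read_newick("((A:1,B:1):1,C:2);")
        ab = AbundanceTable(np.array([[2, 0], [3, 1], [0, 5]], float),
                            ["A", "B", "C"], ["S1", "S2"])
        ba = branch_abundance(tree, ab)
        # the edge above the cherry carries counts(A)+counts(B)
        cherry = [tuple(row) for row in ba.descendant_totals]
        assert (5.0, 1.0) in cherry
        np.testing.assert_array_equal(ba.sample_totals, [5, 6])

    def test_branch_abundance_requires_rooted(self):
        tree = mc.read_newick("(A:1,B:1,C:1);")
        ab = AbundanceTable(np.ones((3, 1)), ["A", "B", "C"], ["S1"])
        with pytest.raises(ValueError, match="midpoint"):
            branch_abundance(tree, ab)

    def test_disjoint_communities_unweighted_one(self):
        tree = mc.read_newick("(A:1,B:2);")
        ab = AbundanceTable(np.array([[3, 0], [0, 4]], float), ["A", "B"],
                            ["S1", "S2"])
        d = unifrac(mc.build_experiment(ab, tree=tree), weighted=False)
        assert d.values[0, 1] == 1.0

    def test_identical_samples_zero_all_variants(self, tiny_exp):
        ab = AbundanceTable(np.array([[2, 2], [1, 1], [3, 3]], float),
                            ["A", "B", "C"], ["S1", "S2"])
        e = mc.build_experiment(ab, tree=tiny_exp.tree)
        for w, n in [(False, False), (True, False), (True, True)]:
            assert unifrac(e, weighted=w, normalized=n).values[0, 1] == 0.0

    def test_hand_derived_three_tip_values(self):
        tree = mc.read_newick("((A:1,B:1):1,C:2);")
        ab = AbundanceTable(np.array([[1, 0, 1], [0, 0, 0], [0, 1, 0]], float),
                            ["A", "B", "C"], ["S1", "S2", "S3"])
        d = unifrac(mc.build_experiment(ab, tree=tree), weighted=False)
        assert d[("S1", "S2")] == pytest.approx(1.0)      # A vs C: no shared branch
        assert d[("S1", "S3")] == pytest.approx(0.0)      # identical
        ab2 = AbundanceTable(np.array([[1, 0], [0, 1], [0, 0]], float),
                             ["A", "B", "C"], ["S1", "S2"])
        d2 = unifrac(mc.build_experiment(ab2, tree=tree), weighted=False)
        assert d2[("S1", "S2")] == pytest.approx(2 / 3)   # A vs B share the stem

    @pytest.mark.parametrize("weighted,normalized",
                             [(False, False), (True, False), (True, True)])
    def test_agrees_with_brute_force_oracle(self, weighted, normalized):
        for seed in range(100):
            e = random_experiment_with_tree(seed)
            d = unifrac(e, weighted=weighted, normalized=normalized)
            for i in range(3):
                for j in range(i + 1, 3):
                    expect = brute_force_unifrac(e, i, j, weighted, normalized)
                    assert d.values[i, j] == pytest.approx(expect, abs=1e-12)

    def test_normalized_variants_in_unit_interval(self):
        for seed in range(30):
            e = random_experiment_with_tree(seed)
            assert unifrac(e, weighted=False).values.max() <= 1 + 1e-12
            assert unifrac(e, weighted=True, normalized=True).values.max() <= 1 + 1e-12

    def test_cross_check_against_scikit_bio(self):
        skbio = pytest.importorskip("skbio")
        from io import StringIO
        from skbio.diversity.beta import unweighted_unifrac, weighted_unifrac
        for seed in range(10):
            e = random_experiment_with_tree(seed)
            sk_tree = skbio.TreeNode.read(StringIO(e.tree.to_newick()))
            counts = e.abundance.values
            mine_u = unifrac(e, weighted=False)
            mine_w = unifrac(e, weighted=True, normalized=False)
            for i, j in [(0, 1), (0, 2), (1, 2)]:
                su = unweighted_unifrac(counts[:, i].astype(int),
                                        counts[:, j].astype(int),
                                        taxa=e.taxon_ids, tree=sk_tree)
                sw = weighted_unifrac(counts[:, i].astype(int),
                                      counts[:, j].astype(int),
                                      taxa=e.taxon_ids, tree=sk_tree)
                assert mine_u.values[i, j] == pytest.approx(su, abs=1e-10)
                assert mine_w.values[i, j] == pytest.approx(sw, abs=1e-10)

    def test_zero_length_branches_contribute_nothing(self):
        tree = mc.read_newick("((A:0,B:1):1,C:2);")
        ab = AbundanceTable(np.array([[1, 0], [0, 1], [1, 1]], float),
                            ["A", "B", "C"], ["S1", "S2"])
        d = unifrac(mc.build_experiment(ab, tree=tree), weighted=False)
        # unique branches: A(0) and B(1); union adds the stem 1 and C 2
        assert d.values[0, 1] == pytest.approx(1 / 4)


class TestParallelContract:
    def test_partitioned_equals_serial_bitwise(self):
        e = mc.simulate_experiment(n_taxa=20, n_samples=50, depth=300, seed=11)
        for method in ("bray", "jsd"):
            serial = distance(e, method, workers=1)
            parallel = distance(e, method, workers=4)
            assert np.array_equal(serial.values, parallel.values)
        su = unifrac(e, weighted=True, normalized=True, workers=1)
        pu = unifrac(e, weighted=True, normalized=True, workers=4)
        assert np.array_equal(su.values, pu.values)


class TestDistanceMatrixType:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix([[0, 1], [2, 0]], ["a", "b"])
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix([[1, 0], [0, 0]], ["a", "b"])
        with pytest.raises(ValueError, match="negative"):
            DistanceMatrix([[0, -1], [-1, 0]], ["a", "b"])
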