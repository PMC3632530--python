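import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

import microcensus as mc
from microcensus.core import AbundanceTable, Experiment
from microcensus.distances import DistanceMatrix, rao_sq
from microcensus.ordination import (
    ca,
    constrained_ordination,
    dpcoa,
    nmds,
    ordinate,
    pca,
    pcoa,
)


def dm(values, labels=None):
    labels = labels or [f"p{i}" for i in range(len(values))]
    return DistanceMatrix(np.asarray(values, float), labels)


class TestCA:
    def test_diagonal_2x2_single_axis_eigenvalue_one(self):
        tab = AbundanceTable(np.array([[10, 0], [0, 10]], float),
                             ["a", "b"], ["x", "y"])
        res = ca(tab)
        assert len(res.eigenvalues) == 1
        assert res.eigenvalues[0] == pytest.approx(1.0)

    def test_rank_one_table_zero_inertia(self):
        u, v = np.array([1.0, 2, 3]), np.array([4.0, 5])
        tab = AbundanceTable(np.outer(u, v), ["a", "b", "c"], ["x", "y"])
        res = ca(tab)
        assert np.all(np.abs(res.eigenvalues) < 1e-12)

    def test_total_inertia_equals_chisq_over_n(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            X = rng.integers(1, 30, size=(4, 5)).astype(float)
            tab = AbundanceTable(X, list("abcd"), list("vwxyz"))
            res = ca(tab)
            N = X.sum()
            E = np.outer(X.sum(1), X.sum(0)) / N
            chi2 = (((X - E) ** 2) / E).sum()
            assert res.extras["total_inertia"] == pytest.approx(chi2 / N, abs=1e-10)

    def test_zero_margin_names_offender(self):
        tab = AbundanceTable(np.array([[1, 0], [2, 0]], float), ["a", "b"], ["x", "y"])
        with pytest.raises(ValueError, match="y"):
            ca(tab)


class TestPCoA:
    def test_recovers_euclidean_distances(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            pts = rng.normal(size=(7, 3))
            D = squareform(pdist(pts))
            res = pcoa(dm(D))
            rec = squareform(pdist(res.sample_coords.values))
            np.testing.assert_allclose(rec, D, atol=1e-8)

    def test_collinear_points_one_positive_eigenvalue(self):
        D = squareform(pdist(np.array([[0.0], [1.0], [3.0]])))
        res = pcoa(dm(D))
        assert np.sum(res.eigenvalues > 1e-9) == 1
        rec = squareform(pdist(res.sample_coords.values))
        np.testing.assert_allclose(rec, D, atol=1e-10)

    def test_equilateral_two_equal_eigenvalues(self):
        D = np.ones((3, 3)) - np.eye(3)
        res = pcoa(dm(D))
        pos = res.eigenvalues[res.eigenvalues > 1e-12]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1])

    def test_two_points_symmetric_split(self):
        res = pcoa(dm([[0, 7], [7, 0]]))
        coords = res.sample_coords.values.ravel()
        assert sorted(np.round(coords, 10)) == [-3.5, 3.5]

    def test_negative_eigenvalues_retained(self):
        # a metric that is not Euclidean-embeddable (violates 4-point cond.)
        D = np.array([[0, 1, 1, 1], [1, 0, 1, 1], [1, 1, 0, 1.9], [1, 1, 1.9, 0]])
        res = pcoa(dm(D))
        assert res.eigenvalues[-1] < 0
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)


class TestNMDS:
    def test_perfect_fit_on_embeddable_input(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(8, 2))
        res = nmds(dm(squareform(pdist(pts))), k=2, n_starts=3, seed=0)
        assert res.stress <= 1e-6

    def test_same_seed_identical_results(self):
        rng = np.random.default_rng(4)
        D = squareform(pdist(rng.random((7, 4))))
        a = nmds(dm(D), seed=9)
        b = nmds(dm(D), seed=9)
        assert a.stress == b.stress
        np.testing.assert_array_equal(a.sample_coords.values, b.sample_coords.values)

    def test_stress_trace_nonincreasing_over_random_inputs(self):
        rng = np.random.default_rng(5)
        for s in range(50):
            R = rng.random((6, 6))
            D = (R + R.T) / 2
            np.fill_diagonal(D, 0)
            res = nmds(dm(D), seed=s, n_starts=2)
            assert np.all(np.diff(res.extras["stress_trace"]) <= 1e-12)

    def test_stress_invariant_under_rotation(self):
        rng = np.random.default_rng(6)
        D = squareform(pdist(rng.random((6, 3))))
        res = nmds(dm(D), seed=1, n_starts=2)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        from microcensus.ordination import _isotonic, _stress1
        X = res.sample_coords.values @ rot
        dvec = dm(D).condensed()
        order = np.argsort(dvec, kind="stable")
        delta = pdist(X)
        dhat = np.empty_like(delta)
        dhat[order] = _isotonic(delta[order])
        assert _stress1(delta, dhat) == pytest.approx(res.stress, abs=1e-10)

    def test_degenerate_all_zero_distances(self):
        with pytest.raises(ValueError, match="degenerate"):
            nmds(dm(np.zeros((4, 4))), seed=0)


class TestPCA:
    def test_line_carries_all_variance(self):
        x = np.arange(5, dtype=float)
        res = pca(np.column_stack([x, 2 * x]))
        props = res.proportions()
        assert props[0] == pytest.approx(1.0)

    def test_eigenvalue_sum_equals_total_variance(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(10, 4))
        res = pca(X)
        assert res.eigenvalues.sum() == pytest.approx(
            X.var(axis=0, ddof=1).sum(), abs=1e-10)

    def test_scaling_gives_rescale_invariance(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(9, 3))
        a = pca(X, scale=True)
        b = pca(X * np.array([10.0, 0.1, 3.0]), scale=True)
        np.testing.assert_allclose(np.abs(a.sample_coords.values),
                                   np.abs(b.sample_coords.values), atol=1e-8)

    def test_zero_variance_column_with_scale_errors(self):
        X = np.column_stack([np.arange(4.0), np.ones(4)])
        with pytest.raises(ValueError, match="variance"):
            pca(X, scale=True)


class TestConstrained:
    def test_rda_inertia_decomposition(self, grouped_exp):
        res = constrained_ordination(grouped_exp, "RDA", ["Group"])
        ex = res.extras
        assert ex["constrained_inertia"] + ex["residual_inertia"] == pytest.approx(
            ex["total_inertia"], abs=1e-8)
        assert ex["constrained_inertia"] <= ex["total_inertia"] + 1e-12

    def test_one_binary_constraint_one_axis(self, grouped_exp):
        for method in ("RDA", "CCA"):
            res = constrained_ordination(grouped_exp, method, ["Group"])
            assert len(res.eigenvalues) == 1

    def test_full_span_constraints_equal_pca(self, grouped_exp):
        # one indicator per sample spans the whole sample space
        import pandas as pd
        samples = grouped_exp.samples.copy()
        samples["ID"] = list(samples.index)
        e = mc.build_experiment(grouped_exp.abundance, samples=samples)
        res = constrained_ordination(e, "RDA", ["ID"])
        ref = pca(grouped_exp.abundance.values.T)
        assert res.extras["constrained_inertia"] == pytest.approx(
            ref.eigenvalues.sum(), abs=1e-8)

    def test_intercept_only_rank_zero(self, grouped_exp):
        import pandas as pd
        samples = grouped_exp.samples.copy()
        samples["const"] = 1.0
        e = mc.build_experiment(grouped_exp.abundance, samples=samples)
        with pytest.raises(ValueError, match="rank 0"):
            constrained_ordination(e, "RDA", ["const"])

    def test_cca_constrained_within_total(self, grouped_exp):
        res = constrained_ordination(grouped_exp, "CCA", ["Group"])
        assert 0 <= res.extras["constrained_inertia"] <= res.extras["total_inertia"]


class TestDPCoA:
    def test_identical_samples_identical_coordinates(self, tiny_exp):
        ab = AbundanceTable(np.array([[2, 2], [1, 1], [3, 3]], float),
                            ["A", "B", "C"], ["S1", "S2"])
        e = mc.build_experiment(ab, tree=tiny_exp.tree)
        res = dpcoa(e)
        np.testing.assert_allclose(res.sample_coords.loc["S1"].values,
                                   res.sample_coords.loc["S2"].values, atol=1e-12)

    def test_full_space_distances_match_rao(self, grouped_exp):
        res = dpcoa(grouped_exp)
        full = res.sample_coords.values
        d2 = rao_sq(grouped_exp)
        n = full.shape[0]
        for i in range(n):
            for j in range(n):
                got = ((full[i] - full[j]) ** 2).sum()
                assert got == pytest.approx(d2[i, j], abs=1e-10)

    def test_star_tree_matches_nonphylogenetic_scaling(self):
        # equal-length star: patristic distance is 2h between any two taxa,
        # so Rao reduces to a fixed multiple of the squared Euclidean
        # distance between relative-abundance profiles
        tree = mc.read_newick("(A:1,B:1,C:1,D:1);")
        rng = np.random.default_rng(9)
        counts = rng.integers(1, 20, size=(4, 5)).astype(float)
        e = mc.build_experiment(
            AbundanceTable(counts, ["A", "B", "C", "D"],
                           [f"s{j}" for j in range(5)]), tree=tree)
        d2 = rao_sq(e)
        P = counts / counts.sum(axis=0)
        for i in range(5):
            for j in range(5):
                expect = ((P[:, i] - P[:, j]) ** 2).sum()  # times 2h/2 with h=1
                assert d2[i, j] == pytest.approx(expect, abs=1e-10)


class TestOrdinate:
    def test_mds_on_unifrac(self, grouped_exp):
        res = ordinate(grouped_exp, "MDS", "unifrac")
        assert res.method == "PCoA"
        assert res.extras["distance"] == "unifrac"
        assert list(res.sample_coords.index) == grouped_exp.sample_ids

    def test_ca_dispatch(self, grouped_exp):
        res = ordinate(grouped_exp, "CA")
        assert res.method == "CA"
        assert res.taxa_coords is not None

    def test_nmds_deterministic_via_dispatch(self, grouped_exp):
        a = ordinate(grouped_exp, "NMDS", "bray", seed=1)
        b = ordinate(grouped_exp, "NMDS", "bray", seed=1)
        assert a.stress == b.stress
        np.testing.assert_array_equal(a.sample_coords.values,
                                      b.sample_coords.values)

    def test_dca_not_implemented(self, grouped_exp):
        with pytest.raises(NotImplementedError, match="DCA"):
            ordinate(grouped_exp, "DCA")

    def test_unsupported_method_lists_options(self, grouped_exp):
        with pytest.raises(ValueError, match="NMDS"):
            ordinate(grouped_exp, "tSNE")

    def test_mds_requires_distance(self, grouped_exp):
        with pytest.raises(ValueError, match="distance"):
            ordinate(grouped_exp, "MDS")
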