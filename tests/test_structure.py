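"""MAF classes, normalization, LD pruning, similarity, PCA, distances,
neighborhoods and reference-based selection."""

import itertools

import numpy as np
import pandas as pd
import pytest

import rarestrat as rs
from rarestrat.structure import (
    SimilarityMatrix,
    PCModel,
    unfolded_freq,
)


def make_ds(genotypes, private=None, genes=None):
    g = np.asarray(genotypes, dtype=np.int8)
    p = g.shape[1]
    return rs.GenotypeDataset(
        genotypes=g,
        sample_ids=np.array([f"s{i}" for i in range(g.shape[0])]),
        subpop_labels=np.array(["x"] * g.shape[0]),
        variants=pd.DataFrame(
            {
                "variant_id": [f"v{j}" for j in range(p)],
                "gene": genes if genes is not None else ["g1"] * p,
                "private": private if private is not None else [False] * p,
            }
        ),
    )


class TestMaf:
    @pytest.mark.parametrize(
        "column, expected",
        [
            ((0, 0, 0, 0), 0.0),
            ((2, 2, 2, 2), 0.0),  # folded
            ((0, 1, 1, 2), 0.5),
            ((0, 0, 0, 1), 0.125),
        ],
    )
    def test_folded_maf(self, column, expected):
        ds = make_ds(np.array(column)[:, None])
        assert rs.compute_maf(ds)[0] == pytest.approx(expected)

    def test_missing_excluded_from_denominator(self):
        ds = make_ds(np.array([[0], [1], [rs.MISSING], [rs.MISSING]]))
        assert rs.compute_maf(ds)[0] == pytest.approx(0.25)

    def test_all_missing_flagged_nan(self):
        ds = make_ds(np.full((3, 1), rs.MISSING))
        assert np.isnan(rs.compute_maf(ds)[0])


class TestClassify:
    def test_boundaries_and_private_exclusion(self):
        mafs = np.array([0.005, 0.01, 0.049, 0.05, 0.2, 0.2, 0.0, np.nan])
        private = np.array([False, False, False, False, False, True, False, False])
        sets = rs.classify_variants(mafs, private)
        assert list(sets["RV"].indices) == [0]
        assert list(sets["LFV"].indices) == [1, 2]
        assert list(sets["CV"].indices) == [3, 4]  # private 0.2 excluded
        assert 5 not in set(np.concatenate([sets[k].indices for k in ("RV", "LFV", "CV")]))
        assert 6 not in set(sets["ALLV"].indices)  # monomorphic
        assert 7 not in set(sets["ALLV"].indices)  # undefined MAF

    def test_partition_property(self, small_cohort):
        mafs = rs.compute_maf(small_cohort)
        sets = rs.classify_variants(mafs, small_cohort.variants["private"].to_numpy())
        parts = [sets[k].indices for k in ("RV", "LFV", "CV")]
        union = np.sort(np.concatenate(parts))
        np.testing.assert_array_equal(union, np.sort(sets["ALLV"].indices))
        for a, b in itertools.combinations(parts, 2):
            assert not set(a) & set(b)


class TestNormalize:
    def test_formula_two_samples(self):
        ds = make_ds([[0], [1]])
        norm = rs.normalize_genotypes(ds, np.array([0]))
        # mu = 0.5, f = 0.25 -> +-0.5 / sqrt(0.1875)
        np.testing.assert_allclose(norm.matrix[:, 0], [-1.1547005, 1.1547005], atol=1e-6)
        assert norm.matrix.mean(axis=0) == pytest.approx(0.0, abs=1e-12)

    def test_constant_heterozygous_column_is_zero(self):
        ds = make_ds([[1], [1], [1]])
        norm = rs.normalize_genotypes(ds, np.array([0]))
        np.testing.assert_allclose(norm.matrix, 0.0)

    def test_monomorphic_column_rejected(self):
        ds = make_ds([[0], [0], [0]])
        with pytest.raises(ValueError, match="monomorphic"):
            rs.normalize_genotypes(ds, np.array([0]))

    def test_unfolded_frequency_used(self):
        # ALT-major column: folded MAF 0.25 but normalization uses f = 0.75
        ds = make_ds([[2], [2], [2], [0]])
        norm = rs.normalize_genotypes(ds, np.array([0]))
        assert norm.freq[0] == pytest.approx(0.75)
        np.testing.assert_allclose(
            norm.matrix[:, 0],
            (np.array([2, 2, 2, 0]) - 1.5) / np.sqrt(0.75 * 0.25),
        )


class TestLdPrune:
    def test_duplicate_columns_keep_one(self):
        col = np.array([0, 1, 2, 0, 1, 2, 1, 0])
        ds = make_ds(np.column_stack([col, col]))
        pruned = rs.ld_prune(ds, np.array([0, 1]), window=None)
        assert len(pruned) == 1

    def test_uncorrelated_set_unchanged(self, rng):
        g = rng.integers(0, 3, size=(200, 12)).astype(np.int8)
        ds = make_ds(g)
        corr = np.corrcoef(g.T) ** 2
        np.fill_diagonal(corr, 0)
        assert corr.max() < 0.2  # fixture sanity
        pruned = rs.ld_prune(ds, np.arange(12), window=None)
        assert len(pruned) == 12

    def test_correlated_triple_matches_exhaustive_search(self, rng):
        # one strongly correlated triple among 10 variants
        base = rng.integers(0, 3, size=300).astype(np.int8)
        noisy1 = base.copy()
        noisy2 = base.copy()
        flip = rng.random(300) < 0.05
        noisy1[flip] = rng.integers(0, 3, size=flip.sum())
        flip2 = rng.random(300) < 0.05
        noisy2[flip2] = rng.integers(0, 3, size=flip2.sum())
        others = rng.integers(0, 3, size=(300, 7)).astype(np.int8)
        g = np.column_stack([base, noisy1, noisy2, others])
        ds = make_ds(g)
        pruned = set(rs.ld_prune(ds, np.arange(10), window=None).indices)

        # oracle: largest subset with all pairwise r^2 <= 0.2
        r2 = np.corrcoef(g.astype(float).T) ** 2
        best = set()
        for k in range(10, 0, -1):
            for subset in itertools.combinations(range(10), k):
                ok = all(r2[i, j] <= 0.2 for i, j in itertools.combinations(subset, 2))
                if ok:
                    best = set(subset)
                    break
            if best:
                break
        assert len(pruned) == len(best)
        for i, j in itertools.combinations(sorted(pruned), 2):
            assert r2[i, j] <= 0.2


class TestSimilarity:
    def test_hand_outer_product(self):
        norm = rs.NormalizedGenotypes(
            matrix=np.array([[-1.0], [1.0]]),
            mu=np.array([0.5]),
            freq=np.array([0.25]),
            variant_indices=np.array([0]),
        )
        sim = rs.similarity_matrix(norm)
        np.testing.assert_allclose(sim.matrix, [[1, -1], [-1, 1]])

    def test_symmetry_trace_and_psd(self, two_pop_cohort):
        mafs = rs.compute_maf(two_pop_cohort)
        sets = rs.classify_variants(mafs, two_pop_cohort.variants["private"].to_numpy())
        norm = rs.normalize_genotypes(two_pop_cohort, sets["CV"])
        sim = rs.similarity_matrix(norm)
        s = sim.matrix
        np.testing.assert_allclose(s, s.T, atol=1e-9)
        assert np.trace(s) == pytest.approx((norm.matrix**2).sum(), rel=1e-10)
        eigs = np.linalg.eigvalsh(s)
        assert eigs.min() > -1e-8 * abs(eigs).max()


class TestPca:
    def test_identity_spectrum(self):
        sim = SimilarityMatrix(np.eye(6), "CV", 1)
        pc = rs.pca(sim, n_components=5)
        np.testing.assert_allclose(pc.eigenvalues, np.ones(5), atol=1e-12)

    def test_eigenvalue_sum_bounded_by_trace(self, two_pop_cohort):
        mafs = rs.compute_maf(two_pop_cohort)
        sets = rs.classify_variants(mafs, two_pop_cohort.variants["private"].to_numpy())
        sim = rs.similarity_matrix(rs.normalize_genotypes(two_pop_cohort, sets["CV"]))
        pc = rs.pca(sim, n_components=10)
        assert np.diff(pc.eigenvalues).max() <= 1e-9  # non-increasing
        assert pc.eigenvalues.sum() <= np.trace(sim.matrix) + 1e-6
        # scores orthogonal with squared norm lambda_k
        gram = pc.scores.T @ pc.scores
        np.testing.assert_allclose(gram, np.diag(pc.eigenvalues), atol=1e-6)

    def test_two_subpop_separation_on_pc1(self, two_pop_cohort):
        pre = rs.pretreat(two_pop_cohort, need_perms=False, need_lmm=False)
        pc1 = pre.pc.scores[:, 0]
        labels = two_pop_cohort.subpop_labels
        side = pc1 > np.median(pc1)
        agreement = max((side == (labels == "A")).mean(), (side == (labels == "B")).mean())
        assert agreement >= 0.99

    def test_component_limit_enforced(self):
        sim = SimilarityMatrix(np.eye(4), "CV", 1)
        with pytest.raises(ValueError):
            rs.pca(sim, n_components=4)


class TestDistance:
    def test_formula_example(self):
        pc = PCModel(
            scores=np.array([[1.0, 0.0], [3.0, 2.0]]), eigenvalues=np.array([4.0, 1.0])
        )
        d2 = rs.genetic_distance(pc, K=2)
        assert d2[0, 1] == pytest.approx(20.0)
        assert d2[0, 0] == 0.0 and d2[1, 0] == d2[0, 1]

    def test_identical_rows_zero(self):
        pc = PCModel(scores=np.ones((3, 2)), eigenvalues=np.array([2.0, 1.0]))
        assert rs.genetic_distance(pc, K=2).max() == 0.0

    def test_triangle_inequality(self, rng):
        pc = PCModel(scores=rng.normal(size=(15, 4)), eigenvalues=np.array([4.0, 3.0, 2.0, 1.0]))
        d = np.sqrt(rs.genetic_distance(pc, K=4))
        for i, j, k in itertools.permutations(range(15), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    def test_full_k_reproduces_weighted_euclidean(self, rng):
        scores = rng.normal(size=(10, 5))
        lam = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        pc = PCModel(scores=scores, eigenvalues=lam)
        d2 = rs.genetic_distance(pc, K=5)
        w = scores * np.sqrt(lam)
        for i in range(10):
            for j in range(10):
                assert d2[i, j] == pytest.approx(((w[i] - w[j]) ** 2).sum(), abs=1e-10)

    def test_k_exceeding_components_rejected(self):
        pc = PCModel(scores=np.ones((3, 2)), eigenvalues=np.array([2.0, 1.0]))
        with pytest.raises(ValueError):
            rs.genetic_distance(pc, K=3)


class TestNeighbors:
    def test_list_length_clipped(self):
        d = np.zeros((3, 3))
        graph = rs.nearest_neighbors(d, N=30)
        assert graph.neighbors.shape == (3, 2)

    def test_tie_rule_lowest_index_first(self):
        d = np.zeros((5, 5))
        graph = rs.nearest_neighbors(d, N=2)
        np.testing.assert_array_equal(graph.neighbors[0], [1, 2])
        np.testing.assert_array_equal(graph.neighbors[3], [0, 1])

    def test_matches_argsort_oracle(self, rng):
        x = rng.normal(size=(20, 3))
        d = ((x[:, None, :] - x[None, :, :]) ** 2).sum(-1)
        graph = rs.nearest_neighbors(d, N=7)
        for i in range(20):
            order = [j for j in np.argsort(d[i], kind="stable") if j != i][:7]
            np.testing.assert_array_equal(graph.neighbors[i], order)
        # neighbor distances non-decreasing within each list
        assert (np.diff(graph.distances, axis=1) >= 0).all()


class TestReferenceSelection:
    @pytest.fixture()
    def pc(self, rng):
        scores = rng.normal(size=(40, 10))
        lam = np.linspace(10, 1, 10)
        return PCModel(scores=scores, eigenvalues=lam, sample_ids=np.array([f"s{i}" for i in range(40)]))

    def test_tiny_threshold_selects_reference_only(self, pc):
        out = rs.select_by_reference_distance(pc, 5, 1e-12)
        assert list(out) == ["s5"]

    def test_infinite_threshold_selects_all(self, pc):
        out = rs.select_by_reference_distance(pc, "s0", np.inf)
        assert len(out) == 40

    def test_threshold_at_kth_distance(self, pc):
        w = pc.scores * np.sqrt(pc.eigenvalues)
        d2 = ((w - w[7]) ** 2).sum(axis=1)
        thr = np.sort(d2)[30]  # 31st smallest (reference itself is 0)
        out = rs.select_by_reference_distance(pc, 7, thr)
        assert len(out) == 30
        assert "s7" in set(out)
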