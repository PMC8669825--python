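import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import jensenshannon

from ptgut.io_tables import TaxaCountTable, read_newick
from ptgut.diversity import RelAbundanceTable
from ptgut.distances import (
    MAX_JS_DISTANCE, jsd_matrix, pcoa_coordinates, permanova,
    unweighted_unifrac, weighted_unifrac,
)
from ptgut.synthetic_cohort import generate_tree


def _relab(rows, taxa=None):
    rows = np.asarray(rows, dtype=float)
    taxa = taxa or [f"t{j}" for j in range(rows.shape[1])]
    return RelAbundanceTable([f"s{i}" for i in range(rows.shape[0])], taxa, rows)


def kl_oracle(p, q):
    """Term-by-term Kullback-Leibler sum with the 0 log 0 convention."""
    total = 0.0
    for pi, qi in zip(p, q):
        if pi > 0:
            total += pi * np.log(pi / qi)
    return total


def js_distance_oracle(a, b):
    m = 0.5 * (np.asarray(a) + np.asarray(b))
    return np.sqrt(0.5 * kl_oracle(a, m) + 0.5 * kl_oracle(b, m))


class TestJSD:
    def test_identical_profiles_zero(self):
        d = jsd_matrix(_relab([[0.2, 0.8], [0.2, 0.8]]))
        assert d.data[0, 1] == 0.0

    def test_disjoint_supports_maximal(self):
        d = jsd_matrix(_relab([[1.0, 0.0], [0.0, 1.0]]))
        assert d.data[0, 1] == pytest.approx(np.sqrt(np.log(2)), abs=1e-12)
        assert MAX_JS_DISTANCE == pytest.approx(np.sqrt(np.log(2)))

    def test_matches_kl_summation_oracle(self):
        a, b = [0.5, 0.5], [1.0, 0.0]
        d = jsd_matrix(_relab([a, b]))
        assert d.data[0, 1] == pytest.approx(js_distance_oracle(a, b), abs=1e-12)

    def test_matches_scipy_on_random_profiles(self):
        rng = np.random.default_rng(3)
        p = rng.dirichlet(np.ones(8) * 0.7, size=6)
        d = jsd_matrix(_relab(p))
        for i in range(6):
            for j in range(6):
                expected = jensenshannon(p[i], p[j], base=np.e)
                assert d.data[i, j] == pytest.approx(expected, abs=1e-10)

    def test_bounded_symmetric_zero_diagonal(self, small_relab):
        d = jsd_matrix(small_relab).data
        assert d.max() <= MAX_JS_DISTANCE + 1e-12
        assert np.allclose(d, d.T, atol=1e-12)
        assert np.allclose(np.diag(d), 0)


# --- UniFrac oracles: independent recursive branch tally ------------------

def _branches(tree):
    """(length, descendant tip set) for every non-root branch."""
    out = []
    for node in tree.traverse(include_self=False):
        tips = {t.name for t in ([node] if node.is_tip() else node.tips())}
        out.append((node.length or 0.0, tips))
    return out


def unweighted_oracle(tree, present_a, present_b):
    shared = unique = 0.0
    for length, tips in _branches(tree):
        in_a = bool(tips & present_a)
        in_b = bool(tips & present_b)
        if in_a and in_b:
            shared += length
        elif in_a or in_b:
            unique += length
    total = shared + unique
    return 0.0 if total == 0 else unique / total


def weighted_oracle(tree, prop_a, prop_b, normalized):
    num = den = 0.0
    for length, tips in _branches(tree):
        a = sum(prop_a.get(t, 0.0) for t in tips)
        b = sum(prop_b.get(t, 0.0) for t in tips)
        num += length * abs(a - b)
        den += length * (a + b)
    if not normalized:
        return num
    return 0.0 if den == 0 else num / den


class TestUnweightedUniFrac:
    def test_identical_presence_zero(self):
        tree = read_newick("(A:1,B:2):0;")
        table = TaxaCountTable(["s1", "s2"], ["A", "B"],
                               np.array([[5, 1], [2, 8]]))
        assert unweighted_unifrac(table, tree).data[0, 1] == 0.0

    def test_star_tree_disjoint_is_one(self):
        tree = read_newick("(A:1,B:1,C:1,D:1):0;")
        table = TaxaCountTable(["s1", "s2"], ["A", "B", "C", "D"],
                               np.array([[5, 3, 0, 0], [0, 0, 2, 2]]))
        assert unweighted_unifrac(table, tree).data[0, 1] == pytest.approx(1.0)

    def test_three_leaf_hand_tally(self):
        tree = read_newick("(A:1,(B:1,C:1):1);")
        table = TaxaCountTable(["s1", "s2"], ["A", "B", "C"],
                               np.array([[1, 1, 0], [1, 0, 1]]))
        got = unweighted_unifrac(table, tree).data[0, 1]
        # branches: A(1, shared), B(1, s1 only), C(1, s2 only),
        # BC-stem(1, shared) -> unique 2 of total 4
        assert got == pytest.approx(0.5)
        assert got == pytest.approx(
            unweighted_oracle(tree, {"A", "B"}, {"A", "C"}))

    def test_missing_taxon_rejected(self):
        tree = read_newick("(A:1,B:1):0;")
        table = TaxaCountTable(["s1"], ["A", "Z"], np.array([[1, 1]]))
        with pytest.raises(Exception, match="absent"):
            unweighted_unifrac(table, tree)

    def test_random_small_trees_match_oracle(self):
        rng = np.random.default_rng(5)
        taxa = list("ABCDE")
        for trial in range(10):
            tree = generate_tree(taxa, seed=trial)
            counts = rng.integers(0, 3, size=(4, 5))
            counts[:, 0] += 1  # no empty samples
            table = TaxaCountTable([f"s{i}" for i in range(4)], taxa, counts)
            dm = unweighted_unifrac(table, tree)
            for i in range(4):
                for j in range(4):
                    pa = {t for t, c in zip(taxa, counts[i]) if c > 0}
                    pb = {t for t, c in zip(taxa, counts[j]) if c > 0}
                    assert dm.data[i, j] == pytest.approx(
                        unweighted_oracle(tree, pa, pb), abs=1e-10)


class TestWeightedUniFrac:
    def test_identical_profiles_zero(self):
        tree = read_newick("(A:1,B:1):0;")
        relab = _relab([[0.3, 0.7], [0.3, 0.7]], taxa=["A", "B"])
        assert weighted_unifrac(relab, tree).data[0, 1] == 0.0

    def test_cherry_full_swap_normalized_one(self):
        # all mass moves from one leaf to the other: maximal dissimilarity
        tree = read_newick("(A:1,B:1):0;")
        relab = _relab([[1.0, 0.0], [0.0, 1.0]], taxa=["A", "B"])
        assert weighted_unifrac(relab, tree, normalized=True).data[0, 1] \
            == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("normalized", [True, False])
    def test_random_small_trees_match_oracle(self, normalized):
        rng = np.random.default_rng(8)
        taxa = list("ABCDE")
        for trial in range(10):
            tree = generate_tree(taxa, seed=100 + trial)
            p = rng.dirichlet(np.ones(5), size=4)
            relab = _relab(p, taxa=taxa)
            dm = weighted_unifrac(relab, tree, normalized=normalized)
            for i in range(4):
                for j in range(4):
                    expected = weighted_oracle(
                        tree, dict(zip(taxa, p[i])), dict(zip(taxa, p[j])),
                        normalized)
                    assert dm.data[i, j] == pytest.approx(expected, abs=1e-10)

    def test_triangle_inequality_on_fixtures(self):
        # the raw branch-weighted sum is a length-weighted L1 distance,
        # hence a metric
        rng = np.random.default_rng(2)
        taxa = list("ABCD")
        tree = generate_tree(taxa, seed=4)
        p = rng.dirichlet(np.ones(4), size=6)
        d = weighted_unifrac(_relab(p, taxa=taxa), tree, normalized=False).data
        n = d.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-12

    def test_matches_skbio_on_integer_counts(self):
        """Cross-check against the scikit-bio implementation where it is
        exact (integer count input)."""
        from skbio.diversity import beta_diversity

        taxa = list("ABCDE")
        tree = generate_tree(taxa, seed=21)
        counts = np.array([[5, 0, 3, 1, 1], [0, 2, 3, 0, 5], [1, 1, 1, 1, 1]])
        relab = _relab(counts / counts.sum(axis=1, keepdims=True), taxa=taxa)
        mine = weighted_unifrac(relab, tree, normalized=True)
        ref = beta_diversity("weighted_unifrac", counts,
                             ids=["s0", "s1", "s2"], taxa=taxa, tree=tree,
                             normalized=True)
        assert np.allclose(mine.data, ref.data, atol=1e-10)


class TestPermanova:
    @staticmethod
    def _euclid_dm(coords):
        from skbio import DistanceMatrix

        coords = np.asarray(coords, dtype=float)
        d = np.abs(coords[:, None] - coords[None, :])
        return DistanceMatrix(d, ids=[f"s{i}" for i in range(len(coords))])

    def test_strong_separation_minimal_p(self):
        # groups big enough that no permutation re-creates the partition
        coords = list(np.arange(10) * 0.01) + list(10 + np.arange(10) * 0.01)
        dm = self._euclid_dm(coords)
        cov = pd.DataFrame({"sample_id": dm.ids,
                            "g": ["a"] * 10 + ["b"] * 10})
        res = permanova(dm, cov, ["g"], n_perm=999, seed=1)
        row = res[res.term == "g"].iloc[0]
        # 1/(n_perm+1): the +1-corrected minimum (no permutation re-creates
        # the two-blob partition under this seed)
        assert row["p"] == pytest.approx(1 / 1000)

    def test_single_factor_r2_matches_ss_oracle(self):
        """R^2 equals 1 - SSW/SST computed from group means of 1-D
        Euclidean coordinates (Gower identity)."""
        coords = np.array([0.0, 1.0, 2.0, 5.0, 6.5, 8.0])
        groups = np.array([0, 0, 0, 1, 1, 1])
        dm = self._euclid_dm(coords)
        cov = pd.DataFrame({"sample_id": dm.ids, "g": groups})
        res = permanova(dm, cov, ["g"], n_perm=99, seed=0)
        sst = ((coords - coords.mean()) ** 2).sum()
        ssw = sum(((coords[groups == g] - coords[groups == g].mean()) ** 2).sum()
                  for g in (0, 1))
        expected_r2 = 1 - ssw / sst
        assert res[res.term == "g"].iloc[0]["R2"] == pytest.approx(expected_r2,
                                                                   abs=1e-10)

    def test_sequential_r2_sums_to_one_with_residual(self, small_relab,
                                                     small_cohort):
        _, meta, _, _ = small_cohort
        dm = jsd_matrix(small_relab)
        cov = meta.for_samples(small_relab.sample_ids)
        res = permanova(dm, cov, ["sex", "chorioamnionitis", "corrected_ga"],
                        n_perm=49, seed=1)
        assert res["R2"].iloc[:-1].sum() == pytest.approx(1.0, abs=1e-9)
        assert (res["R2"] >= -1e-12).all()

    def test_matches_skbio_pseudo_f(self):
        """Single-factor pseudo-F agrees with scikit-bio's PERMANOVA."""
        from skbio.stats.distance import permanova as skbio_permanova

        rng = np.random.default_rng(4)
        coords = rng.normal(size=12)
        dm = self._euclid_dm(coords)
        grouping = ["a", "b"] * 6
        cov = pd.DataFrame({"sample_id": dm.ids, "g": grouping})
        mine = permanova(dm, cov, ["g"], n_perm=99, seed=0)
        ref = skbio_permanova(dm, grouping, permutations=99)
        assert mine[mine.term == "g"].iloc[0]["pseudo_F"] == pytest.approx(
            ref["test statistic"], abs=1e-10)

    def test_constant_factor_rejected(self):
        dm = self._euclid_dm([0.0, 1.0, 2.0, 3.0])
        cov = pd.DataFrame({"sample_id": dm.ids, "g": ["a"] * 4})
        with pytest.raises(ValueError, match="constant"):
            permanova(dm, cov, ["g"], n_perm=9, seed=0)

    def test_bad_n_perm_rejected(self):
        dm = self._euclid_dm([0.0, 1.0, 2.0, 3.0])
        cov = pd.DataFrame({"sample_id": dm.ids, "g": ["a", "a", "b", "b"]})
        with pytest.raises(ValueError, match="n_perm"):
            permanova(dm, cov, ["g"], n_perm=0, seed=0)


def test_pcoa_exports_leading_axes(small_relab):
    dm = jsd_matrix(small_relab)
    coords = pcoa_coordinates(dm, n_axes=3)
    assert list(coords.columns) == ["sample_id", "PC1", "PC2", "PC3"]
    assert len(coords) == len(dm.ids)
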