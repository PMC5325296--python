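import numpy as np
import pandas as pd
import pytest

from riparia.beta import (
    SimilarityMatrix,
    similarity_matrix,
    simprof,
    simprof_test,
    upgma,
)
from riparia.io import ValidationError

from conftest import community_from

INDICES = ("jaccard", "sorensen_quantitative", "morisita_horn")


class TestSimilarityIndices:
    def test_identical_sites_score_100(self):
        m = community_from([[3, 1, 4], [3, 1, 4]])
        for index in INDICES:
            s = similarity_matrix(m, index)
            assert s.values.iloc[0, 1] == pytest.approx(100.0)

    def test_disjoint_sites_score_0(self):
        m = community_from([[3, 1, 0, 0], [0, 0, 2, 5]])
        for index in INDICES:
            assert similarity_matrix(m, index).values.iloc[0, 1] == pytest.approx(0.0)

    def test_hand_case(self):
        # x=(2,0,2), y=(0,2,2): Jaccard 1/3, Sorensen 2W/(X+Y)=4/8, MH 50
        m = community_from([[2, 0, 2], [0, 2, 2]])
        assert similarity_matrix(m, "jaccard").values.iloc[0, 1] == pytest.approx(100 / 3)
        assert similarity_matrix(m, "sorensen_quantitative").values.iloc[0, 1] == pytest.approx(50.0)
        assert similarity_matrix(m, "morisita_horn").values.iloc[0, 1] == pytest.approx(50.0)

    def test_empty_site_rejected(self):
        m = community_from([[1, 2], [0, 0]])
        for index in INDICES:
            with pytest.raises(ValidationError, match="S2"):
                similarity_matrix(m, index)

    def test_unknown_index_rejected(self, toy_community):
        with pytest.raises(ValueError, match="unknown index"):
            similarity_matrix(toy_community, "bray")

    def test_invariant_to_absent_species(self, rng):
        counts = rng.integers(0, 10, size=(4, 8))
        counts[:, 0] += 1  # no empty site
        padded = np.hstack([counts, np.zeros((4, 3), dtype=int)])
        for index in INDICES:
            a = similarity_matrix(community_from(counts), index).values.to_numpy()
            b = similarity_matrix(community_from(padded), index).values.to_numpy()
            assert np.allclose(a, b)

    def test_morisita_horn_scale_invariant_sorensen_not(self):
        base = np.array([[4, 2, 1], [1, 3, 5]])
        scaled = base.copy()
        scaled[0] *= 3
        mh_a = similarity_matrix(community_from(base, samples_per_site=60), "morisita_horn")
        mh_b = similarity_matrix(community_from(scaled, samples_per_site=60), "morisita_horn")
        assert mh_a.values.iloc[0, 1] == pytest.approx(mh_b.values.iloc[0, 1])
        so_a = similarity_matrix(community_from(base, samples_per_site=60), "sorensen_quantitative")
        so_b = similarity_matrix(community_from(scaled, samples_per_site=60), "sorensen_quantitative")
        assert so_a.values.iloc[0, 1] != pytest.approx(so_b.values.iloc[0, 1])

    def test_jaccard_depends_only_on_presence(self, rng):
        counts = rng.integers(0, 10, size=(3, 6))
        counts[:, 0] += 1
        inflated = counts * rng.integers(1, 5, size=counts.shape)
        a = similarity_matrix(community_from(counts), "jaccard").values
        b = similarity_matrix(community_from(inflated, samples_per_site=80), "jaccard").values
        assert np.allclose(a, b)

    def test_symmetry_and_range(self, rng):
        counts = rng.integers(0, 12, size=(6, 10))
        counts[:, 0] += 1
        for index in INDICES:
            s = similarity_matrix(community_from(counts), index)
            arr = s.values.to_numpy()
            assert np.allclose(arr, arr.T)
            assert arr.min() >= 0 and arr.max() <= 100 + 1e-9
            assert np.allclose(np.diag(arr), 100.0)


def sim_from_array(arr, labels=None) -> SimilarityMatrix:
    labels = labels or [chr(65 + i) for i in range(len(arr))]
    return SimilarityMatrix(pd.DataFrame(arr, index=labels, columns=labels), "test")


class TestUpgma:
    def test_hand_three_site_case(self):
        # S(1,2)=80, S(1,3)=40, S(2,3)=20: merge (1,2) at 80, then at (40+20)/2
        s = sim_from_array([[100, 80, 40], [80, 100, 20], [40, 20, 100]])
        tree = upgma(s)
        assert sorted(tree.merge_heights(), reverse=True) == pytest.approx([80.0, 30.0])
        assert sorted(tree.cut(50.0)) == [("A", "B"), ("C",)]

    def test_tied_similarities_deterministic(self):
        s = sim_from_array(np.where(np.eye(4), 100.0, 50.0))
        t1, t2 = upgma(s), upgma(s)
        assert t1.to_newick() == t2.to_newick()
        assert all(h == pytest.approx(50.0) for h in t1.merge_heights())
        # lexicographic tie-break: the deepest merge joins the first two labels
        deepest = t1.root
        while not deepest.children[0].is_leaf:
            deepest = deepest.children[0]
        assert deepest.leaves == (0, 1)

    def test_matches_scipy_average_linkage(self, rng):
        from scipy.cluster.hierarchy import linkage

        for _ in range(50):
            n = 6
            d = rng.uniform(5, 95, size=(n, n))
            d = (d + d.T) / 2
            sim = 100 - d
            np.fill_diagonal(sim, 100.0)
            tree = upgma(sim_from_array(sim))
            iu = np.triu_indices(n, k=1)
            z = linkage(d[iu], method="average")
            ours = sorted(100.0 - h for h in tree.merge_heights())
            ref = sorted(float(h) for h in z[:, 2])
            assert ours == pytest.approx(ref, abs=1e-8)

    def test_newick_parses_and_is_ultrametric(self):
        s = sim_from_array([[100, 80, 40], [80, 100, 20], [40, 20, 100]])
        nwk = upgma(s).to_newick()
        import io as _io

        from Bio import Phylo

        tree = Phylo.read(_io.StringIO(nwk), "newick")
        depths = tree.depths()
        leaf_depths = [d for c, d in depths.items() if c.is_terminal()]
        assert len(leaf_depths) == 3
        # all leaves equidistant from root: (100 - root similarity) / 2
        assert leaf_depths == pytest.approx([35.0, 35.0, 35.0])


class TestSimprof:
    def test_identical_sites_never_rejected(self):
        m = community_from([[4, 2, 1]] * 5)
        res = simprof(m, "sorensen_quantitative", n_perm_mean=50, n_perm_null=99, seed=0)
        assert res.n_significant == 0
        assert res.partition == [tuple(m.site_ids)]
        assert all(t.pi_stat == pytest.approx(0.0) for t in res.tests)

    def test_two_disjoint_blocks_rejected_at_floor(self):
        block_a = [[6, 6, 6, 0, 0, 0]] * 3
        block_b = [[0, 0, 0, 6, 6, 6]] * 3
        m = community_from(block_a + block_b)
        res = simprof(m, "sorensen_quantitative", n_perm_mean=100, n_perm_null=199, seed=1)
        root = res.tests[0]
        assert root.rejected
        assert root.p_value == pytest.approx(1 / 200)
        assert sorted(res.partition) == [("S1", "S2", "S3"), ("S4", "S5", "S6")]

    def test_p_value_never_zero(self, rng):
        counts = rng.integers(0, 12, size=(5, 8))
        counts[:, 0] += 1
        m = community_from(counts)
        res = simprof(m, "jaccard", n_perm_mean=30, n_perm_null=49, seed=2)
        assert all(t.p_value >= 1 / 50 for t in res.tests)

    def test_too_few_sites_rejected(self):
        m = community_from([[1, 2], [2, 1]])
        with pytest.raises(ValidationError):
            simprof(m)

    def test_deterministic_under_seed(self, rng):
        counts = rng.integers(0, 10, size=(6, 9))
        counts[:, 0] += 1
        m = community_from(counts)
        r1 = simprof(m, "morisita_horn", n_perm_mean=40, n_perm_null=99, seed=7)
        r2 = simprof(m, "morisita_horn", n_perm_mean=40, n_perm_null=99, seed=7)
        assert [(t.pi_stat, t.p_value) for t in r1.tests] == [
            (t.pi_stat, t.p_value) for t in r2.tests
        ]
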