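import io

import numpy as np
import pandas as pd
import pytest

from pigpop import fst
from pigpop.containers import MISSING, ParameterError
from pigpop.synthetic import drift_frequencies, simulate_population
from conftest import matrix_from
from oracles import theta_anova_oracle


class TestPerLocusTheta:
    def test_fixed_difference_is_one(self):
        assert fst.per_locus_fst(np.array([[6, 0, 0], [0, 0, 8]])).theta == pytest.approx(1.0)

    def test_identical_populations_near_zero(self):
        res = fst.per_locus_fst(np.array([[4, 8, 4], [4, 8, 4]]))
        assert res.theta <= 1e-12  # estimator is <= 0 for identical samples

    def test_worked_example_matches_anova_oracle(self):
        counts = np.array([[8, 2, 0], [1, 4, 5]])
        assert fst.per_locus_fst(counts).theta == pytest.approx(
            theta_anova_oracle(counts), abs=1e-12
        )

    def test_monomorphic_locus_undefined(self):
        assert np.isnan(fst.per_locus_fst(np.array([[5, 0, 0], [7, 0, 0]])).theta)

    def test_single_informative_population_rejected(self):
        with pytest.raises(ParameterError):
            fst.per_locus_fst(np.array([[5, 1, 0], [0, 0, 0]]))

    def test_theta_one_iff_fixed_difference(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            counts = rng.integers(0, 6, size=(2, 3))
            if (counts.sum(axis=1) > 0).sum() < 2:
                continue
            theta = fst.per_locus_fst(counts).theta
            fixed_diff = (
                counts[0, 1] == 0
                and counts[1, 1] == 0
                and counts[0].sum() > 1
                and counts[1].sum() > 1
                and ((counts[0, 0] > 0) != (counts[1, 0] > 0))
                and ((counts[0, 2] > 0) != (counts[1, 2] > 0))
                and (counts[0, 0] + counts[1, 0] > 0)
                and (counts[0, 2] + counts[1, 2] > 0)
            )
            if fixed_diff:
                assert theta == pytest.approx(1.0, abs=1e-12)
            elif not np.isnan(theta):
                assert theta < 1.0 + 1e-12


class TestPairwiseFst:
    def _two_pop_matrix(self, calls_a, calls_b):
        calls = np.vstack([calls_a, calls_b]).astype(np.int8)
        pops = {f"s{i + 1}": ("A" if i < len(calls_a) else "B") for i in range(len(calls))}
        return matrix_from(calls, populations=pops)

    def test_same_samples_near_zero(self):
        # duplicating the very same individuals leaves zero between-pop
        # variance; WC84 then has a small O(1/n) negative bias, so the
        # estimate sits just below zero at large n
        rng = np.random.default_rng(12)
        calls = rng.integers(0, 3, size=(200, 300))
        g = self._two_pop_matrix(calls, calls)
        est = fst.pairwise_fst(g, "A", "B")
        assert est <= 0.0
        assert abs(est) < 0.01

    def test_identical_frequencies_near_zero(self):
        rng = np.random.default_rng(13)
        freqs = rng.uniform(0.2, 0.8, 3_000)
        a = simulate_population(freqs, 20, 0.0, rng)
        b = simulate_population(freqs, 20, 0.0, rng)
        g = self._two_pop_matrix(a, b)
        assert abs(fst.pairwise_fst(g, "A", "B")) < 0.01

    def test_all_fixed_differences_is_one(self):
        a = np.zeros((5, 50), dtype=np.int8)
        b = np.full((5, 50), 2, dtype=np.int8)
        g = self._two_pop_matrix(a, b)
        assert fst.pairwise_fst(g, "A", "B") == pytest.approx(1.0)

    def test_locus_order_and_monomorphic_invariance(self):
        rng = np.random.default_rng(14)
        a = rng.integers(0, 3, size=(8, 100))
        b = rng.integers(0, 3, size=(8, 100))
        g = self._two_pop_matrix(a, b)
        base = fst.pairwise_fst(g, "A", "B")
        perm = rng.permutation(100)
        assert fst.pairwise_fst(g, "A", "B", loci=perm) == pytest.approx(base, abs=1e-12)
        # append a monomorphic locus
        calls = np.hstack([g.calls, np.zeros((16, 1), dtype=np.int8)])
        g2 = matrix_from(calls, populations=g.populations)
        assert fst.pairwise_fst(g2, "A", "B") == pytest.approx(base, abs=1e-12)


class TestDendrogram:
    def _matrix(self, labels, d):
        return pd.DataFrame(d, index=labels, columns=labels)

    def test_nearest_pair_joins_first(self):
        m = self._matrix(
            ["A", "B", "C"], [[0, 0.05, 0.30], [0.05, 0, 0.30], [0.30, 0.30, 0]]
        )
        tree = fst.fst_dendrogram(m)
        assert "(A:0.025,B:0.025)" in tree

    def test_upgma_reproduces_ultrametric_distances(self):
        labels = ["A", "B", "C", "D"]
        d = np.array(
            [
                [0.0, 0.2, 0.6, 0.6],
                [0.2, 0.0, 0.6, 0.6],
                [0.6, 0.6, 0.0, 0.4],
                [0.6, 0.6, 0.4, 0.0],
            ]
        )
        tree = fst.fst_dendrogram(self._matrix(labels, d))
        from skbio import TreeNode

        t = TreeNode.read(io.StringIO(tree))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    assert t.find(a).distance(t.find(b)) == pytest.approx(d[i, j], abs=1e-9)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(15)
        labels = list("ABCDE")
        d = rng.uniform(0.1, 0.5, (5, 5))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        m = self._matrix(labels, d)
        shuffled = m.loc[["D", "A", "E", "B", "C"], ["D", "A", "E", "B", "C"]]
        assert fst.fst_dendrogram(m) == fst.fst_dendrogram(shuffled)

    def test_nested_drift_recovers_designed_clusters(self):
        """Populations drifted from two diverged ancestors group by ancestor."""
        rng = np.random.default_rng(16)
        base = rng.uniform(0.05, 0.95, 4_000)
        anc1 = drift_frequencies(base, 0.15, rng)
        anc2 = drift_frequencies(base, 0.15, rng)
        calls, pops = [], {}
        layout = {"A1": anc1, "A2": anc1, "B1": anc2, "B2": anc2}
        sample = 0
        for name, anc in layout.items():
            fr = drift_frequencies(anc, 0.02, rng)
            g = simulate_population(fr, 10, 0.0, rng)
            for _ in range(10):
                sample += 1
                pops[f"s{sample}"] = name
            calls.append(g)
        g = matrix_from(np.vstack(calls), populations=pops)
        tree = fst.fst_dendrogram(fst.fst_matrix(g))
        from skbio import TreeNode

        t = TreeNode.read(io.StringIO(tree))
        tip_sets = [
            frozenset(x.name for x in n.tips()) for n in t.non_tips(include_self=True)
        ]
        assert frozenset({"A1", "A2"}) in tip_sets
        assert frozenset({"B1", "B2"}) in tip_sets

    def test_incomplete_matrix_rejected(self):
        m = self._matrix(["A", "B"], [[0, np.nan], [np.nan, 0]])
        with pytest.raises(ParameterError):
            fst.fst_dendrogram(m)

    def test_nj_emits_newick(self):
        m = self._matrix(
            ["A", "B", "C"], [[0, 0.05, 0.30], [0.05, 0, 0.30], [0.30, 0.30, 0]]
        )
        tree = fst.fst_dendrogram(m, method="nj")
        assert tree.endswith(";") and "A" in tree
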