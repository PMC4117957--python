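import numpy as np
import pandas as pd
import pytest

from pigpop import diversity as dv
from pigpop.containers import MISSING, CallabilityTrack, VariantTable
from pigpop.synthetic import simulate_population, simulate_callability_track, simulate_variant_table
from conftest import matrix_from
from oracles import f_oracle, he_oracle, ho_oracle


class TestObservedHeterozygosity:
    def test_all_heterozygous_gives_one(self):
        g = matrix_from(np.ones((3, 4), dtype=np.int8))
        assert dv.observed_heterozygosity(g)["P"] == 1.0

    def test_direct_count_example(self):
        # 2 individuals, 2 loci: genotypes (0,1) and (1,2) -> one het per locus
        g = matrix_from(np.array([[0, 1], [1, 2]], dtype=np.int8))
        assert dv.observed_heterozygosity(g)["P"] == pytest.approx(0.5)

    def test_fully_missing_locus_excluded(self):
        g = matrix_from(np.array([[1, MISSING], [1, MISSING]], dtype=np.int8))
        assert dv.observed_heterozygosity(g)["P"] == 1.0


class TestExpectedHeterozygosity:
    def test_monomorphic_locus_contributes_zero(self):
        g = matrix_from(np.zeros((4, 3), dtype=np.int8))
        assert dv.expected_heterozygosity(g)["P"] == 0.0

    def test_small_sample_correction_by_hand(self):
        # p = 0.5 with n = 2 diploids: (2n/(2n-1)) * 2pq = (4/3) * 0.5
        g = matrix_from(np.array([[0], [2]], dtype=np.int8))
        assert dv.expected_heterozygosity(g)["P"] == pytest.approx(4 / 3 * 0.5, abs=1e-12)

    def test_large_n_limit_is_2pq(self):
        n = 4000
        geno = np.array([0] * (n // 4) + [1] * (n // 2) + [2] * (n // 4), dtype=np.int8)
        g = matrix_from(geno[:, None])
        assert dv.expected_heterozygosity(g)["P"] == pytest.approx(0.5, abs=1e-3)


class TestInbreedingCoefficient:
    def test_fully_homozygous_individual(self):
        geno = np.array([[0, 2, 0, 2], [0, 1, 1, 2], [1, 1, 0, 0]], dtype=np.int8)
        g = matrix_from(geno)
        assert dv.inbreeding_coefficient(g, "s1") == pytest.approx(1.0)

    def test_matches_bruteforce_on_random_matrix(self):
        rng = np.random.default_rng(2)
        geno = rng.integers(0, 3, size=(6, 40)).astype(np.int8)
        geno[rng.random(geno.shape) < 0.1] = MISSING
        g = matrix_from(geno)
        for i, s in enumerate(g.sample_ids):
            assert dv.inbreeding_coefficient(g, s) == pytest.approx(
                f_oracle(geno, i), abs=1e-12, nan_ok=True
            )

    def test_admixed_individual_negative_f(self):
        # individual heterozygous everywhere in an otherwise differentiated cohort
        rng = np.random.default_rng(3)
        a = simulate_population(np.full(2_000, 0.05), 10, 0.0, rng)
        b = simulate_population(np.full(2_000, 0.95), 10, 0.0, rng)
        admixed = np.ones((1, 2_000), dtype=np.int8)
        g = matrix_from(np.vstack([a, b, admixed]))
        assert dv.inbreeding_coefficient(g, "s21") < 0

    def test_ho_he_match_bruteforce(self):
        rng = np.random.default_rng(4)
        geno = rng.integers(0, 3, size=(8, 30)).astype(np.int8)
        geno[rng.random(geno.shape) < 0.15] = MISSING
        g = matrix_from(geno)
        assert dv.observed_heterozygosity(g)["P"] == pytest.approx(ho_oracle(geno), abs=1e-12)
        assert dv.expected_heterozygosity(g)["P"] == pytest.approx(he_oracle(geno), abs=1e-12)


class TestBinnedHeterozygosity:
    def _track(self, callable_per_tile, tile_bp=10_000, mean_depth=10.0):
        arr = np.asarray(callable_per_tile, dtype=np.int64)
        return CallabilityTrack(tile_bp, {"1": tile_bp * len(arr)}, {"1": arr}, mean_depth)

    def _table(self, positions, genotypes, depth=10):
        df = pd.DataFrame(
            {
                "chrom": "1",
                "pos": positions,
                "ref": "A",
                "alt": "C",
                "genotype": genotypes,
                "depth": depth,
                "snp_quality": 50.0,
                "variant_type": "snp",
                "functional_class": "synonymous",
                "damage_label": "none",
            }
        )
        return VariantTable("x", df)

    def test_bin_arithmetic(self):
        # one 50-kb bin, fully callable, 100 het sites -> h = 2e-3
        track = self._track([10_000] * 5)
        vt = self._table(np.arange(100) * 400, np.ones(100, dtype=int))
        bins, h = dv.binned_heterozygosity(vt, track)
        assert h == pytest.approx(100 / 50_000)

    def test_low_depth_het_not_counted(self):
        track = self._track([10_000] * 5)
        vt = self._table([100, 200], [1, 1], depth=6)
        _, h = dv.binned_heterozygosity(vt, track)
        assert h == 0.0

    def test_uncovered_bin_dropped_not_zero(self):
        # second 50-kb bin has no callable sites: dropped, not h = 0
        track = self._track([10_000] * 5 + [0] * 5)
        vt = self._table(np.arange(50) * 900, np.ones(50, dtype=int))
        bins, h = dv.binned_heterozygosity(vt, track)
        assert len(bins) == 1
        assert h == pytest.approx(50 / 50_000)

    def test_invariant_full_callability_recovers_density(self):
        # with every site callable, expected h equals het density per bp
        rng = np.random.default_rng(5)
        L = 2_000
        positions = np.sort(rng.choice(1_000_000, L, replace=False))
        geno = (rng.random(L) < 0.3).astype(int)
        track = self._track([10_000] * 100)
        vt = self._table(positions, geno)
        _, h = dv.binned_heterozygosity(vt, track)
        dens = geno.sum() / 1_000_000
        assert h == pytest.approx(dens, rel=0.15)


class TestConcordance:
    def _summary(self, pop_df, ind_df):
        return dv.DiversitySummary(pop_df, ind_df)

    def test_perfect_and_anti_correlation(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        pop = pd.DataFrame({"population": list("abcd"), "Ho": x, "He": -x, "F": x, "h_ngs": x})
        ind = pd.DataFrame({"individual": list("abcd"), "population": list("abcd"), "F": -x, "h_ngs": x})
        out = dv.concordance(self._summary(pop, ind)).set_index("pair")
        assert out.loc["Ho~h_NGS", "r"] == pytest.approx(1.0)
        assert out.loc["He~h_NGS", "r"] == pytest.approx(-1.0)
        assert out.loc["F~h_NGS", "r"] == pytest.approx(-1.0)

    def test_constant_vector_reported_nan(self):
        pop = pd.DataFrame(
            {"population": list("abc"), "Ho": [0.2] * 3, "He": [0.2] * 3, "F": [0.1, 0.2, 0.3], "h_ngs": [1, 2, 3]}
        )
        ind = pop.rename(columns={"population": "individual"}).assign(population="p")
        out = dv.concordance(self._summary(pop, ind)).set_index("pair")
        assert np.isnan(out.loc["Ho~h_NGS", "r"])


def test_he_exceeds_ho_under_inbreeding():
    rng = np.random.default_rng(6)
    freqs = rng.uniform(0.05, 0.95, 5_000)
    g = matrix_from(simulate_population(freqs, 30, 0.3, rng))
    ho = dv.observed_heterozygosity(g)["P"]
    he = dv.expected_heterozygosity(g)["P"]
    assert he > ho
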