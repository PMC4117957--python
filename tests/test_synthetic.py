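import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pigpop.containers import MISSING, ParameterError
from pigpop import roh
from pigpop.synthetic import (
    SimConfig,
    drift_frequencies,
    implant_roh,
    merge_intervals,
    merged_plan,
    simulate_callability_track,
    simulate_population,
    simulate_qtl_set,
    simulate_study,
    simulate_variant_table,
    unique_sorted_positions,
)
from conftest import matrix_from


class TestSimulatePopulation:
    @pytest.mark.parametrize(
        "f,p,expected_het",
        [(0.0, 0.5, 0.5), (0.5, 0.5, 0.25), (0.2, 0.3, 2 * 0.3 * 0.7 * 0.8)],
    )
    def test_het_fraction_matches_closed_form(self, f, p, expected_het):
        n, L = 200, 500
        g = simulate_population(np.full(L, p), n, f, seed=3)
        het = (g == 1).mean()
        se = np.sqrt(expected_het * (1 - expected_het) / (n * L))
        assert abs(het - expected_het) < 3 * se

    def test_complete_inbreeding_gives_no_heterozygotes(self):
        g = simulate_population(np.random.default_rng(0).uniform(0, 1, 300), 50, 1.0, seed=4)
        assert (g == 1).sum() == 0

    @pytest.mark.parametrize("bad", [{"f": -0.1}, {"f": 1.5}, {"n": 0}])
    def test_invalid_parameters_rejected(self, bad):
        kwargs = {"freqs": np.array([0.5]), "n": 5, "f": 0.2, "seed": 0}
        kwargs.update(bad)
        with pytest.raises(ParameterError):
            simulate_population(**kwargs)

    def test_bad_frequencies_rejected(self):
        with pytest.raises(ParameterError):
            simulate_population(np.array([0.5, 1.2]), 5, 0.0, seed=0)


class TestImplantRoh:
    def test_planned_interval_fully_homozygous(self):
        g = matrix_from(simulate_population(np.full(60, 0.5), 1, 0.0, seed=1))
        out = implant_roh(g, [("s1", "1", 0, 400_000)], np.full(60, 0.5), seed=2)
        inside = out.markers["pos"] < 400_000
        assert np.isin(out.calls[0, inside.to_numpy()], (0, 2)).all()
        # outside untouched
        outside = ~inside.to_numpy()
        assert np.array_equal(out.calls[0, outside], g.calls[0, outside])

    def test_empty_plan_is_identity(self):
        g = matrix_from(simulate_population(np.full(30, 0.5), 2, 0.0, seed=1))
        assert implant_roh(g, [], np.full(30, 0.5), seed=9).equals(g)

    def test_abutting_intervals_merge_into_one_run(self):
        pos = np.arange(100) * 10_000  # dense 10-kb spacing
        g = matrix_from(np.ones(100, dtype=np.int8), pos=pos)  # all het
        plan = [("s1", "1", 100_000, 300_000), ("s1", "1", 300_000, 500_000)]
        out = implant_roh(g, plan, np.full(100, 0.5), seed=5)
        assert merged_plan(plan)["s1"] == [("1", 100_000, 500_000)]
        calls = roh.call_roh_chip(out, "s1", min_snps=10, max_het=0, min_len=50_000)
        spanning = [r for r in calls if r.start <= 100_000 and r.end >= 490_001]
        assert len(spanning) == 1


class TestVariantTable:
    def test_poisson_depth_mean(self):
        L = 20_000
        rng = np.random.default_rng(6)
        vt = simulate_variant_table(
            "x", np.zeros(L, dtype=np.int8), np.repeat("1", L),
            np.arange(L) * 100, np.repeat("A", L), np.repeat("C", L), 10.0, rng,
        )
        assert abs(vt.records["depth"].mean() - 10.0) < 0.5

    def test_low_depth_genome_mostly_uncallable(self):
        rng = np.random.default_rng(7)
        track = simulate_callability_track({"1": 2_000_000}, 2.0, rng)
        frac = track.total_callable() / track.genome_size()
        assert frac < 0.05  # P(depth >= 7 | mean 2) ~ 0.0045

    def test_fixed_seed_reproduces_table(self):
        args = (
            "x", np.zeros(500, dtype=np.int8), np.repeat("1", 500),
            np.arange(500) * 100, np.repeat("A", 500), np.repeat("C", 500), 10.0,
        )
        a = simulate_variant_table(*args, np.random.default_rng(42))
        b = simulate_variant_table(*args, np.random.default_rng(42))
        pd.testing.assert_frame_equal(a.records, b.records)


class TestQtlSet:
    CHROMS = {"1": 10_000_000}

    def test_full_enrichment_covers_every_snp(self):
        snps = [("1", int(p)) for p in np.linspace(1e5, 9e6, 10)]
        qtls = simulate_qtl_set(
            10, (100_000, 300_000), self.CHROMS, snps, 1.0, np.random.default_rng(0)
        )
        from pigpop.overlap import overlap_count

        assert overlap_count(snps, qtls, "qtl") == 10

    def test_null_enrichment_overlap_matches_coverage(self):
        rng = np.random.default_rng(1)
        qtls = simulate_qtl_set(20, (200_000, 200_000), self.CHROMS, [], 0.0, rng)
        merged = merge_intervals(
            [(s, e) for s, e in zip(qtls.intervals["start"], qtls.intervals["end"])]
        )
        coverage = sum(e - s for s, e in merged) / 10_000_000
        snps = [("1", int(p)) for p in rng.integers(0, 10_000_000, 400)]
        from pigpop.overlap import overlap_count

        obs = overlap_count(snps, qtls, "qtl")
        se = np.sqrt(400 * coverage * (1 - coverage))
        assert abs(obs - 400 * coverage) < 4 * se

    def test_empty_set(self):
        qtls = simulate_qtl_set(0, (100_000, 200_000), self.CHROMS, [], 0.0, np.random.default_rng(2))
        from pigpop.overlap import overlap_count

        assert len(qtls) == 0
        assert overlap_count([("1", 5)], qtls, "qtl") == 0

    def test_interval_longer_than_chromosome_rejected(self):
        with pytest.raises(ParameterError):
            simulate_qtl_set(1, (100, 20_000_000), self.CHROMS, [], 0.0, np.random.default_rng(3))


class TestStudyGroundTruth:
    def test_implanted_roh_homozygous_in_emitted_genotypes(self, study):
        chroms = study.chip.markers["chrom"].to_numpy()
        pos = study.chip.markers["pos"].to_numpy()
        for ind, intervals in study.truth.implanted_roh.items():
            row = study.chip.calls[study.chip.sample_index(ind)]
            for chrom, s, e in intervals:
                inside = (chroms == chrom) & (pos >= s) & (pos < e)
                vals = row[inside]
                assert not (vals == 1).any()  # hom or missing only

    def test_enriched_snps_are_emitted_nonsynonymous(self, study):
        vt = next(iter(study.variant_tables.values()))
        nonsyn = set(zip(vt.nonsynonymous()["chrom"], vt.nonsynonymous()["pos"]))
        assert set(study.truth.enriched_snps) <= nonsyn

    def test_study_is_seed_deterministic(self):
        cfg = SimConfig(n_snps_chip=400, n_snps_seq=5_000, n_fixed_per_breed=3, seed=5)
        a = simulate_study(cfg)
        b = simulate_study(cfg)
        assert np.array_equal(a.chip.calls, b.chip.calls)
        sid = next(iter(a.variant_tables))
        pd.testing.assert_frame_equal(a.variant_tables[sid].records, b.variant_tables[sid].records)
        pd.testing.assert_frame_equal(a.qtls.intervals, b.qtls.intervals)
        pd.testing.assert_frame_equal(a.truth.fixed_differences, b.truth.fixed_differences)


@given(
    st.lists(
        st.tuples(st.integers(0, 1000), st.integers(1, 200)).map(lambda t: (t[0], t[0] + t[1])),
        max_size=20,
    )
)
@settings(deadline=None, max_examples=60, derandomize=True)
def test_merge_intervals_covers_same_points(intervals):
    merged = merge_intervals(intervals)
    # sorted, disjoint with gaps
    assert all(merged[i][1] < merged[i + 1][0] for i in range(len(merged) - 1))
    for x in range(0, 1201, 7):
        in_raw = any(s <= x < e for s, e in intervals)
        in_merged = any(s <= x < e for s, e in merged)
        assert in_raw == in_merged


@given(st.integers(1, 10_000), st.integers(0, 50))
@settings(deadline=None, max_examples=40, derandomize=True)
def test_unique_sorted_positions_properties(length, n):
    n = min(n, length)
    pos = unique_sorted_positions(length, n, np.random.default_rng(0))
    assert len(pos) == n == len(np.unique(pos))
    assert (np.diff(pos) > 0).all() if n > 1 else True
    assert ((pos >= 0) & (pos < length)).all()


def test_drift_preserves_mean_frequency():
    rng = np.random.default_rng(8)
    base = np.full(20_000, 0.3)
    drifted = drift_frequencies(base, 0.1, rng)
    assert ((drifted >= 0) & (drifted <= 1)).all()
    assert abs(drifted.mean() - 0.3) < 0.01
    assert abs(drifted.var() - 0.1 * 0.3 * 0.7) < 0.002
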