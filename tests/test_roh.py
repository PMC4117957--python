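import numpy as np
import pandas as pd
import pytest

from pigpop import roh
from pigpop.containers import CallabilityTrack, MISSING, PigpopError, RohInterval, RohSet, VariantTable
from conftest import matrix_from
from oracles import chip_roh_oracle


def _call_chip(geno, pos, **kw):
    g = matrix_from(np.asarray(geno, dtype=np.int8), pos=np.asarray(pos))
    return roh.call_roh_chip(g, "s1", **kw)


class TestChipCaller:
    def test_clean_homozygous_run_called(self):
        pos = np.arange(25) * 20_000  # 480-kb span
        calls = _call_chip(np.zeros(25), pos)
        assert len(calls) == 1
        r = calls.intervals[0]
        assert (r.start, r.end, r.n_snps) == (0, 480_001, 25)

    def test_below_min_snps_not_called(self):
        pos = np.arange(19) * 20_000
        assert len(_call_chip(np.zeros(19), pos)) == 0

    def test_two_hets_break_segment_both_sides_reported(self):
        geno = np.zeros(25)
        geno[10] = geno[14] = 1
        pos = np.arange(25) * 20_000
        calls = _call_chip(geno, pos, min_snps=5)
        expected = chip_roh_oracle(pos, geno.astype(int), min_snps=5)
        assert {(r.start, r.end) for r in calls} == expected
        assert len(calls) == 2  # [0, before 2nd het] and [after 1st het, end]

    def test_gap_splits_blocks(self):
        pos = np.concatenate([np.arange(25) * 20_000, 2_000_000 + np.arange(25) * 20_000])
        calls = _call_chip(np.zeros(50), pos)
        assert len(calls) == 2

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(10)
        for _ in range(40):
            n = int(rng.integers(10, 60))
            pos = np.sort(rng.choice(5_000_000, n, replace=False))
            geno = rng.choice([0, 1, 2, MISSING], size=n, p=[0.45, 0.12, 0.4, 0.03])
            kw = dict(min_snps=5, max_het=1, min_len=30_000, min_density=0.0, max_gap=800_000)
            got = {(r.start, r.end) for r in _call_chip(geno, pos, **kw)}
            exp = chip_roh_oracle(pos, geno, **kw)
            assert got == exp, (pos.tolist(), geno.tolist())

    def test_min_snps_monotonicity(self, study):
        sid = next(iter(study.variant_tables))
        lo = roh.call_roh_chip(study.chip, sid, min_snps=19)
        hi = roh.call_roh_chip(study.chip, sid, min_snps=20)
        assert len(lo) >= len(hi)
        assert lo.union_bp() >= hi.union_bp()


def _ngs_inputs(bin_counts, bin_bp=100_000, callable_ok=None):
    """Build a VariantTable + track whose per-bin het counts equal bin_counts."""
    n_bins = len(bin_counts)
    positions, genos = [], []
    for b, c in enumerate(bin_counts):
        positions.extend(b * bin_bp + 10 + np.arange(c) * 7)
        genos.extend([1] * c)
    df = pd.DataFrame(
        {
            "chrom": "1",
            "pos": positions,
            "ref": "A",
            "alt": "C",
            "genotype": genos,
            "depth": 10,
            "snp_quality": 50.0,
            "variant_type": "snp",
            "functional_class": "synonymous",
            "damage_label": "none",
        }
    )
    tile_bp = 10_000
    tiles = np.full(n_bins * bin_bp // tile_bp, tile_bp, dtype=np.int64)
    if callable_ok is not None:
        for b, ok in enumerate(callable_ok):
            if not ok:
                tiles[b * bin_bp // tile_bp : (b + 1) * bin_bp // tile_bp] = 0
    track = CallabilityTrack(tile_bp, {"1": n_bins * bin_bp}, {"1": tiles}, 10.0)
    return VariantTable("x", df), track


class TestNgsCaller:
    def test_uniform_density_yields_no_roh(self):
        vt, track = _ngs_inputs([20] * 40)
        assert len(roh.call_roh_ngs(vt, track)) == 0

    def test_low_density_stretch_called(self):
        counts = [20] * 20 + [2] * 15 + [20] * 20
        vt, track = _ngs_inputs(counts)
        calls = roh.call_roh_ngs(vt, track)
        assert len(calls) == 1
        r = calls.intervals[0]
        assert (r.start, r.end) == (20 * 100_000, 35 * 100_000)

    def test_nine_bins_below_min_consecutive(self):
        counts = [20] * 20 + [2] * 9 + [20] * 20
        vt, track = _ngs_inputs(counts)
        assert len(roh.call_roh_ngs(vt, track)) == 0

    def test_uncallable_bin_breaks_chain(self):
        counts = [20] * 10 + [0] * 21 + [20] * 10
        ok = [True] * 10 + [True] * 10 + [False] + [True] * 10 + [True] * 10
        vt, track = _ngs_inputs(counts, callable_ok=ok)
        calls = roh.call_roh_ngs(vt, track)
        assert len(calls) == 2

    def test_zero_average_is_degenerate(self):
        vt, track = _ngs_inputs([0] * 40)
        with pytest.raises(PigpopError):
            roh.call_roh_ngs(vt, track)

    def test_density_fraction_monotonicity(self, study):
        sid = next(iter(study.variant_tables))
        vt, track = study.variant_tables[sid], study.tracks[sid]
        lens = [
            roh.call_roh_ngs(vt, track, bin_bp=10_000, density_fraction=f).union_bp()
            for f in (0.1, 0.25, 0.5)
        ]
        assert lens[0] <= lens[1] <= lens[2]

    def test_min_consecutive_monotonicity(self, study):
        sid = next(iter(study.variant_tables))
        vt, track = study.variant_tables[sid], study.tracks[sid]
        counts = [
            len(roh.call_roh_ngs(vt, track, bin_bp=10_000, min_consecutive=m))
            for m in (5, 10, 20)
        ]
        assert counts[0] >= counts[1] >= counts[2]


class TestComparison:
    def test_identical_sets_jaccard_one(self):
        ivs = [("1", 0, 100), ("2", 50, 500)]
        assert roh.interval_jaccard(ivs, ivs) == 1.0

    def test_disjoint_sets_jaccard_zero(self):
        assert roh.interval_jaccard([("1", 0, 100)], [("1", 200, 300)]) == 0.0

    def test_genome_fraction_counts_overlaps_once(self):
        rohs = RohSet(
            [
                RohInterval("i", "1", 0, 100_000, 5, "chip"),
                RohInterval("i", "1", 50_000, 150_000, 5, "chip"),
            ]
        )
        assert roh.roh_genome_fraction(rohs, 1_000_000) == pytest.approx(0.15)

    def test_chip_underestimates_in_roh_rich_genome(self):
        """With a ROH-rich genome and low background inbreeding the chip
        caller covers less of the genome than the sequence caller and
        misses the short stratum, as dense sequence data reveals."""
        from pigpop.synthetic import SimConfig, PopulationSpec, simulate_study

        cfg = SimConfig(
            populations=[PopulationSpec("P", 4, f=0.05)],
            n_roh_long=5,
            n_roh_short=40,  # real ROH landscapes are dominated by short runs
            n_fixed_per_breed=0,
            n_decoy_local_missing=0,
            n_decoy_commercial_missing=0,
            n_snps_seq=60_000,
            seed=21,
        )
        study = simulate_study(cfg)
        chip_fracs, seq_fracs = [], []
        for sid, vt in study.variant_tables.items():
            chip = roh.call_roh_chip(study.chip, sid)
            seq = roh.call_roh_ngs(vt, study.tracks[sid], bin_bp=10_000)
            gs = cfg.genome_bp
            chip_fracs.append(chip.union_bp() / gs)
            seq_fracs.append(seq.union_bp() / gs)
        assert np.mean(chip_fracs) < np.mean(seq_fracs)
        assert np.corrcoef(chip_fracs, seq_fracs)[0, 1] > 0
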