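"""Synthetic cohorts with known ground truth.

The generator emulates the study design this pipeline targets: a dozen
pig breeds genotyped on a ~60K SNP chip, one or two animals per local
breed re-sequenced to ~10x depth alongside a pooled commercial group, an
outgroup (warthog-like) genome for allele polarization, and published
QTL interval sets.  Everything is scaled to a toy genome (default
2 chromosomes x 50 Mb) so a full study simulates in seconds, while the
per-locus processes keep their real-data structure:

* genotypes are drawn per locus under inbreeding ``f`` with
  ``P(hom-ref) = p^2 + f p q``, ``P(het) = 2 p q (1 - f)``,
  ``P(hom-alt) = q^2 + f p q`` (p = reference allele frequency);
* population differentiation comes from Balding-Nichols beta drift
  around shared base frequencies, giving tunable FST;
* runs of homozygosity are implanted as intervals forced homozygous;
* sequencing depth is Poisson around a target mean, with genotypes
  masked outside the callable window, and a per-tile callability track;
* a subset of sequence SNPs is labelled non-synonymous, some of which
  are implanted as fixed differences between commercial and local
  groups (with decoy loci carrying disqualifying missing data);
* QTL intervals are placed uniformly except a controllable fraction
  forced to cover chosen SNPs (enrichment).

There is no coalescent, recombination or mutation model: ROH and fixed
differences exist by implantation, not pedigree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    MARKER_COLUMNS,
    MISSING,
    VARIANT_COLUMNS,
    CallabilityTrack,
    GenotypeMatrix,
    ParameterError,
    QTLSet,
    VariantTable,
)

DAMAGE_LABELS = ("benign", "possibly_damaging", "probably_damaging")
DAMAGE_PROBS = (0.60, 0.25, 0.15)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PopulationSpec:
    """One simulated breed."""

    name: str
    n_samples: int
    f: float  # target inbreeding coefficient per individual
    drift: float = 0.0  # Balding-Nichols differentiation parameter in [0, 1)
    n_sequenced: int | None = None  # defaults to all samples
    role: str = "local"  # "local" | "commercial"

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 1.0:
            raise ParameterError(f"population {self.name}: f must lie in [0, 1]")
        if not 0.0 <= self.drift < 1.0:
            raise ParameterError(f"population {self.name}: drift must lie in [0, 1)")
        if self.n_samples < 1:
            raise ParameterError(f"population {self.name}: n_samples must be >= 1")
        if self.n_sequenced is None:
            self.n_sequenced = self.n_samples


@dataclass
class SimConfig:
    """Study-scale knobs.

    Defaults describe the demo cohort: a 2 x 50 Mb toy genome carrying
    60K-chip-density markers (~24/Mb) and 1 sequence SNP per kb, one
    commercial pool of eight ~10x-sequenced pigs and two local breeds
    with two sequenced animals each.
    """

    n_chromosomes: int = 2
    chrom_length_bp: int = 50_000_000
    n_snps_chip: int = 2_400
    n_snps_seq: int = 100_000
    freq_low: float = 0.05
    freq_high: float = 0.95
    populations: list[PopulationSpec] = field(
        default_factory=lambda: [
            PopulationSpec("Commercial", 8, f=0.15, drift=0.05, role="commercial"),
            PopulationSpec("LocalA", 2, f=0.30, drift=0.15),
            PopulationSpec("LocalB", 2, f=0.50, drift=0.20),
        ]
    )
    mean_depth: float = 10.0
    # ROH implantation: per sequenced individual, long and short segments
    n_roh_long: int = 3
    roh_long_range: tuple[int, int] = (1_500_000, 4_000_000)
    n_roh_short: int = 6
    roh_short_range: tuple[int, int] = (120_000, 190_000)
    # chip noise
    chip_missing_rate: float = 0.005
    chip_bad_marker_fraction: float = 0.01
    chip_bad_marker_missing_rate: float = 0.10
    # sequence annotation / noise
    nonsyn_fraction: float = 0.02
    indel_fraction: float = 0.03
    low_quality_fraction: float = 0.02
    callable_floor: int = 7  # het-scan callability window
    emit_floor: int = 5  # genotype-emission window
    tile_bp: int = 10_000
    # fixed-difference implantation
    n_fixed_per_breed: int = 12
    derived_fixed_local_fraction: float = 0.64
    n_decoy_local_missing: int = 3
    n_decoy_commercial_missing: int = 3
    outgroup_het_rate: float = 0.02
    outgroup_missing_rate: float = 0.05
    # QTLs: category -> (n_intervals, enrichment fraction)
    qtl_categories: dict[str, tuple[int, float]] = field(
        default_factory=lambda: {
            "exterior": (30, 0.8),
            "production": (30, 0.5),
            "meat_quality": (30, 0.0),
            "vertebra": (20, 0.0),
        }
    )
    qtl_length_range: tuple[int, int] = (200_000, 2_000_000)
    gene_length_bp: int = 20_000
    n_background_genes: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.chrom_length_bp < 1:
            raise ParameterError("genome dimensions must be positive")
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ParameterError("duplicate population names")

    @property
    def chrom_names(self) -> list[str]:
        return [str(i + 1) for i in range(self.n_chromosomes)]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length_bp for c in self.chrom_names}

    @property
    def genome_bp(self) -> int:
        return self.n_chromosomes * self.chrom_length_bp


@dataclass
class GroundTruth:
    """What the generator actually put into the data."""

    base_freqs_chip: np.ndarray
    base_freqs_seq: np.ndarray
    pop_freqs_chip: dict[str, np.ndarray]
    pop_freqs_seq: dict[str, np.ndarray]
    true_f: dict[str, float]
    implanted_roh: dict[str, list[tuple[str, int, int]]]
    fixed_differences: pd.DataFrame  # chrom,pos,local_breed,commercial_allele,local_allele,ancestral_allele,derived_fixed_in
    enriched_snps: list[tuple[str, int]]
    ancestral_is_alt: np.ndarray  # per seq locus


@dataclass
class SimulatedStudy:
    config: SimConfig
    chip: GenotypeMatrix
    variant_tables: dict[str, VariantTable]
    tracks: dict[str, CallabilityTrack]
    outgroup: VariantTable
    qtls: QTLSet
    genes: pd.DataFrame  # chrom,start,end,name
    truth: GroundTruth

    def sequenced_individuals(self) -> list[str]:
        return list(self.variant_tables)

    def groups(self) -> tuple[dict[str, list[str]], list[str]]:
        """(local breed -> sequenced individuals, commercial individuals)."""
        local: dict[str, list[str]] = {}
        commercial: list[str] = []
        for spec in self.config.populations:
            seq = [s for s in self.variant_tables if self.chip.populations[s] == spec.name]
            if spec.role == "commercial":
                commercial.extend(seq)
            else:
                local[spec.name] = seq
        return local, commercial


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def unique_sorted_positions(length: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """n distinct sorted 0-based positions on [0, length)."""
    if n > length:
        raise ParameterError(f"cannot place {n} sites on {length} bp")
    pos = np.unique(rng.integers(0, length, size=int(n * 1.05) + 16))
    while len(pos) < n:
        pos = np.unique(np.concatenate([pos, rng.integers(0, length, size=n)]))
    return np.sort(rng.choice(pos, size=n, replace=False))


def draw_base_frequencies(
    n: int, rng: np.random.Generator, low: float = 0.05, high: float = 0.95
) -> np.ndarray:
    """Alternate-allele frequencies, uniform on [low, high]."""
    return rng.uniform(low, high, size=n)


def drift_frequencies(base: np.ndarray, drift: float, rng: np.random.Generator) -> np.ndarray:
    """Balding-Nichols beta perturbation of base frequencies.

    ``drift`` plays the role of the FST-like differentiation parameter:
    p' ~ Beta(p (1-c)/c, (1-p)(1-c)/c) keeps E[p'] = p with variance
    c p (1-p).  drift=0 returns the base frequencies unchanged.
    """
    if drift == 0.0:
        return base.copy()
    scale = (1.0 - drift) / drift
    return rng.beta(np.maximum(base * scale, 1e-9), np.maximum((1.0 - base) * scale, 1e-9))


def simulate_population(
    freqs: np.ndarray, n: int, f: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``n`` diploid genotypes per locus under inbreeding ``f``.

    With probability ``f`` an individual is autozygous at a locus and
    receives a homozygote by allele frequency; otherwise a
    Hardy-Weinberg draw.  This equals the genotype distribution
    P(het) = 2pq(1-f), P(hom-alt) = q^2 + f p q exactly.
    Returns an ``int8`` array of shape (n, n_loci) with 0/1/2 codes.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.min() < 0.0 or freqs.max() > 1.0:
        raise ParameterError("allele frequencies must lie in [0, 1]")
    if not 0.0 <= f <= 1.0:
        raise ParameterError("f must lie in [0, 1]")
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = _rng(seed)
    L = len(freqs)
    hwe = rng.binomial(2, freqs[None, :], size=(n, L)).astype(np.int8)
    autoz = rng.random((n, L)) < f
    hom = (2 * rng.binomial(1, freqs[None, :], size=(n, L))).astype(np.int8)
    return np.where(autoz, hom, hwe).astype(np.int8)


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or abutting half-open intervals."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _implant_rows(
    calls: np.ndarray,
    row: int,
    chroms: np.ndarray,
    positions: np.ndarray,
    intervals: list[tuple[str, int, int]],
    freqs: np.ndarray,
    rng: np.random.Generator,
) -> None:
    for chrom, start, end in intervals:
        mask = (chroms == chrom) & (positions >= start) & (positions < end)
        idx = np.nonzero(mask)[0]
        if len(idx):
            calls[row, idx] = (2 * rng.binomial(1, freqs[idx])).astype(np.int8)


def implant_roh(
    g: GenotypeMatrix,
    plan: Sequence[tuple[str, str, int, int]],
    freqs: np.ndarray,
    seed: int | np.random.Generator,
) -> GenotypeMatrix:
    """Force homozygosity inside planned intervals.

    ``plan`` holds (individual, chrom, start, end) half-open intervals;
    overlapping or abutting intervals of one individual are merged
    before application.  Inside each interval the individual becomes
    homozygous for an allele drawn per locus from ``freqs`` (alternate
    allele frequency per marker); genotypes outside are untouched.
    """
    rng = _rng(seed)
    calls = g.calls.copy()
    chroms = g.markers["chrom"].to_numpy()
    positions = g.markers["pos"].to_numpy()
    per_ind: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for ind, chrom, start, end in plan:
        if start < 0 or end <= start:
            raise ParameterError(f"bad ROH interval {chrom}:{start}-{end}")
        per_ind.setdefault(ind, {}).setdefault(chrom, []).append((start, end))
    for ind, by_chrom in per_ind.items():
        row = g.sample_index(ind)
        merged = [
            (chrom, s, e)
            for chrom, ivs in by_chrom.items()
            for s, e in merge_intervals(ivs)
        ]
        _implant_rows(calls, row, chroms, positions, merged, np.asarray(freqs, float), rng)
    return GenotypeMatrix(list(g.sample_ids), dict(g.populations), g.markers.copy(), calls)


def merged_plan(
    plan: Sequence[tuple[str, str, int, int]]
) -> dict[str, list[tuple[str, int, int]]]:
    """Per-individual merged (chrom, start, end) intervals."""
    per_ind: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for ind, chrom, start, end in plan:
        per_ind.setdefault(ind, {}).setdefault(chrom, []).append((start, end))
    return {
        ind: [
            (chrom, s, e)
            for chrom in sorted(by_chrom)
            for s, e in merge_intervals(by_chrom[chrom])
        ]
        for ind, by_chrom in per_ind.items()
    }


# ---------------------------------------------------------------------------
# sequencing emulation
# ---------------------------------------------------------------------------

def simulate_callability_track(
    chrom_lengths: dict[str, int],
    mean_depth: float,
    rng: np.random.Generator,
    tile_bp: int = 10_000,
    depth_floor: int = 7,
) -> CallabilityTrack:
    """Per-tile callable-site counts under i.i.d. Poisson per-base depth.

    The number of bases in a tile whose Poisson(mean_depth) depth lands
    in [depth_floor, 2 x mean_depth] is Binomial(tile size, q), which is
    drawn directly instead of simulating every base.
    """
    if mean_depth <= 0:
        raise ParameterError("mean_depth must be positive")
    ceiling = int(np.floor(2.0 * mean_depth))
    # empty window (ceiling below floor) means nothing is callable
    q = max(
        stats.poisson.cdf(ceiling, mean_depth) - stats.poisson.cdf(depth_floor - 1, mean_depth),
        0.0,
    )
    counts = {}
    for chrom, length in chrom_lengths.items():
        n_tiles = -(-length // tile_bp)
        sizes = np.full(n_tiles, tile_bp, dtype=np.int64)
        if length % tile_bp:
            sizes[-1] = length % tile_bp
        counts[chrom] = rng.binomial(sizes, q)
    return CallabilityTrack(tile_bp, dict(chrom_lengths), counts, float(mean_depth))


def simulate_variant_table(
    individual_id: str,
    genotypes: np.ndarray,
    chroms: np.ndarray,
    positions: np.ndarray,
    ref: np.ndarray,
    alt: np.ndarray,
    mean_depth: float,
    rng: np.random.Generator,
    nonsyn_mask: np.ndarray | None = None,
    indel_mask: np.ndarray | None = None,
    low_quality_fraction: float = 0.02,
    emit_floor: int = 5,
    forced_callable: np.ndarray | None = None,
    forced_dropout: np.ndarray | None = None,
) -> VariantTable:
    """Emit one individual's variant-call table.

    Depth is Poisson(mean_depth) per site; the genotype is masked to
    missing outside the emission window [emit_floor, 2 x mean_depth].
    ``forced_callable`` / ``forced_dropout`` index sites whose depth is
    pinned inside / outside the window (used to implant controlled
    missing-data patterns).
    """
    if mean_depth <= 0:
        raise ParameterError("mean_depth must be positive")
    L = len(genotypes)
    depth = rng.poisson(mean_depth, size=L)
    if forced_callable is not None and len(forced_callable):
        depth[forced_callable] = int(round(mean_depth))
    if forced_dropout is not None and len(forced_dropout):
        depth[forced_dropout] = 0
    ceiling = 2.0 * mean_depth
    callable_site = (depth >= emit_floor) & (depth <= ceiling)
    geno = np.where(callable_site, genotypes, MISSING).astype(np.int8)

    quality = rng.uniform(20.0, 60.0, size=L)
    low_q = rng.random(L) < low_quality_fraction
    quality[low_q] = rng.uniform(5.0, 19.5, size=int(low_q.sum()))
    if forced_callable is not None and len(forced_callable):
        quality[forced_callable] = 50.0

    if nonsyn_mask is None:
        nonsyn_mask = np.zeros(L, dtype=bool)
    if indel_mask is None:
        indel_mask = np.zeros(L, dtype=bool)
    func = np.where(nonsyn_mask, "non-synonymous", "synonymous")
    func = np.where(indel_mask, "other", func)
    damage = np.where(
        nonsyn_mask,
        rng.choice(DAMAGE_LABELS, size=L, p=DAMAGE_PROBS),
        "none",
    )
    records = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions,
            "ref": ref,
            "alt": alt,
            "genotype": geno,
            "depth": depth,
            "snp_quality": quality,
            "variant_type": np.where(indel_mask, "indel", "snp"),
            "functional_class": func,
            "damage_label": damage,
        }
    )[VARIANT_COLUMNS]
    return VariantTable(individual_id, records)


# ---------------------------------------------------------------------------
# QTL intervals
# ---------------------------------------------------------------------------

def simulate_qtl_set(
    n_intervals: int,
    length_range: tuple[int, int],
    chrom_lengths: dict[str, int],
    enriched_snps: Sequence[tuple[str, int]],
    enrichment: float,
    rng: np.random.Generator,
    category: str = "qtl",
) -> QTLSet:
    """Place QTL intervals uniformly, forcing a fraction to cover SNPs.

    ``enrichment`` of the intervals are anchored on SNPs cycled from
    ``enriched_snps`` (shuffled), the rest are uniform on the genome.
    """
    if not 0.0 <= enrichment <= 1.0:
        raise ParameterError("enrichment must lie in [0, 1]")
    lo, hi = length_range
    if hi > min(chrom_lengths.values()):
        raise ParameterError("QTL length exceeds chromosome length")
    chroms = list(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    n_forced = int(round(enrichment * n_intervals))
    anchors: list[tuple[str, int]] = []
    if n_forced and enriched_snps:
        shuffled = list(enriched_snps)
        rng.shuffle(shuffled)
        anchors = [shuffled[i % len(shuffled)] for i in range(n_forced)]
    rows = []
    for i in range(n_intervals):
        length = int(rng.integers(lo, hi + 1))
        if i < len(anchors):
            chrom, snp_pos = anchors[i]
            L = chrom_lengths[chrom]
            low = max(0, snp_pos - length + 1)
            high = min(snp_pos, L - length)
            start = int(rng.integers(low, high + 1)) if high >= low else max(0, snp_pos - length + 1)
        else:
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            L = chrom_lengths[chrom]
            start = int(rng.integers(0, L - length + 1))
        rows.append((chrom, start, start + length, category, f"QTL_{category}_{i + 1}"))
    return QTLSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "category", "name"]))


# ---------------------------------------------------------------------------
# the full study
# ---------------------------------------------------------------------------

def _apply_missing(calls: np.ndarray, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    calls = calls.copy()
    drop = rng.random(calls.shape) < cfg.chip_missing_rate
    bad = rng.random(calls.shape[1]) < cfg.chip_bad_marker_fraction
    drop |= bad[None, :] & (rng.random(calls.shape) < cfg.chip_bad_marker_missing_rate)
    calls[drop] = MISSING
    return calls


def _roh_plan_for(
    cfg: SimConfig, individuals: Sequence[str], rng: np.random.Generator
) -> list[tuple[str, str, int, int]]:
    plan = []
    for ind in individuals:
        taken: dict[str, list[tuple[int, int]]] = {c: [] for c in cfg.chrom_names}
        specs = [cfg.roh_long_range] * cfg.n_roh_long + [cfg.roh_short_range] * cfg.n_roh_short
        for lo, hi in specs:
            for _ in range(200):  # rejection-sample a non-overlapping slot
                length = int(rng.integers(lo, hi + 1))
                chrom = cfg.chrom_names[int(rng.integers(cfg.n_chromosomes))]
                start = int(rng.integers(0, cfg.chrom_length_bp - length + 1))
                iv = (start, start + length)
                pad = 500_000  # keep implants separated so truth intervals stay distinct
                if all(iv[1] + pad <= s or e + pad <= iv[0] for s, e in taken[chrom]):
                    taken[chrom].append(iv)
                    plan.append((ind, chrom, iv[0], iv[1]))
                    break
    return plan


def simulate_study(cfg: SimConfig | None = None, seed: int | None = None) -> SimulatedStudy:
    """Generate the full synthetic study described by ``cfg``.

    Deterministic given ``cfg.seed`` (``seed`` overrides it).
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    chrom_names = cfg.chrom_names
    per_chrom_chip = np.diff(np.linspace(0, cfg.n_snps_chip, cfg.n_chromosomes + 1).astype(int))
    per_chrom_seq = np.diff(np.linspace(0, cfg.n_snps_seq, cfg.n_chromosomes + 1).astype(int))

    def build_map(per_chrom: np.ndarray, prefix: str) -> pd.DataFrame:
        frames = []
        bases = np.array(["A", "C", "G", "T"])
        for chrom, n in zip(chrom_names, per_chrom):
            pos = unique_sorted_positions(cfg.chrom_length_bp, int(n), rng)
            ref = bases[rng.integers(0, 4, size=int(n))]
            alt = bases[(np.searchsorted(bases, ref) + rng.integers(1, 4, size=int(n))) % 4]
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": pos,
                        "id": [f"{prefix}_{chrom}_{p}" for p in pos],
                        "ref": ref,
                        "alt": alt,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)[MARKER_COLUMNS]

    chip_map = build_map(per_chrom_chip, "chip")
    seq_map = build_map(per_chrom_seq, "seq")

    base_chip = draw_base_frequencies(len(chip_map), rng, cfg.freq_low, cfg.freq_high)
    base_seq = draw_base_frequencies(len(seq_map), rng, cfg.freq_low, cfg.freq_high)

    # per-population frequencies and genotypes
    sample_ids: list[str] = []
    populations: dict[str, str] = {}
    true_f: dict[str, float] = {}
    pop_freqs_chip: dict[str, np.ndarray] = {}
    pop_freqs_seq: dict[str, np.ndarray] = {}
    chip_rows, seq_rows, seq_ids = [], [], []
    for spec in cfg.populations:
        fc = drift_frequencies(base_chip, spec.drift, rng)
        fs = drift_frequencies(base_seq, spec.drift, rng)
        pop_freqs_chip[spec.name] = fc
        pop_freqs_seq[spec.name] = fs
        chip_rows.append(simulate_population(fc, spec.n_samples, spec.f, rng))
        seq_rows.append(simulate_population(fs, spec.n_samples, spec.f, rng))
        for i in range(spec.n_samples):
            sid = f"{spec.name}_{i + 1}"
            sample_ids.append(sid)
            populations[sid] = spec.name
            true_f[sid] = spec.f
            if i < spec.n_sequenced:
                seq_ids.append(sid)
    chip_calls = np.vstack(chip_rows)
    seq_calls = np.vstack(seq_rows)

    # implant ROH into both marker systems for sequenced individuals
    plan = _roh_plan_for(cfg, seq_ids, rng)
    implanted = merged_plan(plan)
    chip_chroms = chip_map["chrom"].to_numpy()
    chip_pos = chip_map["pos"].to_numpy()
    seq_chroms = seq_map["chrom"].to_numpy()
    seq_pos = seq_map["pos"].to_numpy()
    for ind, intervals in implanted.items():
        row = sample_ids.index(ind)
        _implant_rows(chip_calls, row, chip_chroms, chip_pos, intervals, base_chip, rng)
        _implant_rows(seq_calls, row, seq_chroms, seq_pos, intervals, base_seq, rng)

    # annotation masks on sequence loci
    L = len(seq_map)
    indel_mask = rng.random(L) < cfg.indel_fraction
    nonsyn_mask = (rng.random(L) < cfg.nonsyn_fraction) & ~indel_mask

    # implant fixed differences and decoys on non-synonymous loci
    local_breeds = [p.name for p in cfg.populations if p.role != "commercial" and (p.n_sequenced or 0) >= 2]
    commercial_ids = [
        s for s in seq_ids if any(p.name == populations[s] and p.role == "commercial" for p in cfg.populations)
    ]
    ancestral_is_alt = np.zeros(L, dtype=bool)  # ancestral allele is REF by default
    nonsyn_idx = np.nonzero(nonsyn_mask)[0]
    rng.shuffle(nonsyn_idx)
    cursor = 0
    forced_callable: dict[str, list[int]] = {s: [] for s in seq_ids}
    forced_dropout: dict[str, list[int]] = {s: [] for s in seq_ids}
    implant_rows_truth = []
    for breed in local_breeds:
        breed_ids = [s for s in seq_ids if populations[s] == breed][:2]
        n_take = cfg.n_fixed_per_breed + cfg.n_decoy_local_missing
        loci = nonsyn_idx[cursor : cursor + n_take]
        cursor += n_take
        for j, locus in enumerate(loci):
            # commercial pool homozygous ref, breed homozygous alt
            for s in commercial_ids:
                seq_calls[sample_ids.index(s), locus] = 0
                forced_callable[s].append(int(locus))
            for s in breed_ids:
                seq_calls[sample_ids.index(s), locus] = 2
                forced_callable[s].append(int(locus))
            is_decoy = j >= cfg.n_fixed_per_breed
            if is_decoy:
                # knock out one of the two local animals: breed must be skipped
                victim = breed_ids[int(rng.integers(len(breed_ids)))]
                forced_callable[victim].remove(int(locus))
                forced_dropout[victim].append(int(locus))
            else:
                derived_local = rng.random() < cfg.derived_fixed_local_fraction
                # local side is fixed for ALT; if the local allele is the
                # derived one, the ancestral allele is REF (and vice versa)
                ancestral_is_alt[locus] = not derived_local
                implant_rows_truth.append((breed, int(locus), derived_local))
    # commercial-missingness decoys: would-be fixed loci with >3 commercial dropouts
    decoy_comm = nonsyn_idx[cursor : cursor + cfg.n_decoy_commercial_missing]
    cursor += cfg.n_decoy_commercial_missing
    for locus in decoy_comm:
        for s in commercial_ids:
            seq_calls[sample_ids.index(s), locus] = 0
        for breed in local_breeds:
            for s in [x for x in seq_ids if populations[x] == breed][:2]:
                seq_calls[sample_ids.index(s), locus] = 2
                forced_callable[s].append(int(locus))
        victims = rng.choice(len(commercial_ids), size=min(4, len(commercial_ids)), replace=False)
        for vi, s in enumerate(commercial_ids):
            if vi in victims:
                forced_dropout[s].append(int(locus))
            else:
                forced_callable[s].append(int(locus))

    # chip noise + matrix
    chip = GenotypeMatrix(
        sample_ids, populations, chip_map, _apply_missing(chip_calls, cfg, rng)
    )

    # variant tables + callability tracks for sequenced individuals
    variant_tables: dict[str, VariantTable] = {}
    tracks: dict[str, CallabilityTrack] = {}
    ref_arr = seq_map["ref"].to_numpy()
    alt_arr = seq_map["alt"].to_numpy()
    for sid in seq_ids:
        row = sample_ids.index(sid)
        variant_tables[sid] = simulate_variant_table(
            sid,
            seq_calls[row],
            seq_chroms,
            seq_pos,
            ref_arr,
            alt_arr,
            cfg.mean_depth,
            rng,
            nonsyn_mask=nonsyn_mask,
            indel_mask=indel_mask,
            low_quality_fraction=cfg.low_quality_fraction,
            emit_floor=cfg.emit_floor,
            forced_callable=np.array(sorted(set(forced_callable[sid])), dtype=int),
            forced_dropout=np.array(sorted(set(forced_dropout[sid])), dtype=int),
        )
        tracks[sid] = simulate_callability_track(
            cfg.chrom_lengths, cfg.mean_depth, rng, cfg.tile_bp, cfg.callable_floor
        )

    # outgroup: homozygous for the ancestral allele, with noise
    anc_geno = np.where(ancestral_is_alt, 2, 0).astype(np.int8)
    het = rng.random(L) < cfg.outgroup_het_rate
    anc_geno[het] = 1
    outgroup = simulate_variant_table(
        "Warthog",
        anc_geno,
        seq_chroms,
        seq_pos,
        ref_arr,
        alt_arr,
        cfg.mean_depth,
        rng,
        nonsyn_mask=nonsyn_mask,
        indel_mask=indel_mask,
        low_quality_fraction=0.0,
        emit_floor=cfg.emit_floor,
    )
    og = outgroup.records
    drop = rng.random(len(og)) < cfg.outgroup_missing_rate
    og.loc[drop, "genotype"] = MISSING

    # ground-truth fixed differences: a direct pass over the emitted state
    truth_fd = _true_fixed_differences(
        cfg, sample_ids, populations, seq_map, seq_calls, variant_tables,
        nonsyn_mask, local_breeds, commercial_ids, ancestral_is_alt,
    )

    # QTLs anchored on the true screened SNP positions
    enriched = [
        (seq_chroms[i], int(seq_pos[i]))
        for i in sorted({int(r[1]) for r in implant_rows_truth})
    ]
    qtl_frames = []
    for cat, (n_int, enr) in cfg.qtl_categories.items():
        qtl_frames.append(
            simulate_qtl_set(
                n_int, cfg.qtl_length_range, cfg.chrom_lengths, enriched, enr, rng, cat
            ).intervals
        )
    qtls = QTLSet(pd.concat(qtl_frames, ignore_index=True))

    # genes: one around every true fixed-difference locus, plus background
    gene_rows = []
    half = cfg.gene_length_bp // 2
    for k, (chrom, pos) in enumerate(enriched):
        s = max(0, pos - half)
        gene_rows.append((chrom, s, s + cfg.gene_length_bp, f"GENE_FD{k + 1}"))
    for k in range(cfg.n_background_genes):
        chrom = chrom_names[int(rng.integers(cfg.n_chromosomes))]
        s = int(rng.integers(0, cfg.chrom_length_bp - cfg.gene_length_bp))
        gene_rows.append((chrom, s, s + cfg.gene_length_bp, f"GENE_BG{k + 1}"))
    genes = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "name"]).sort_values(
        ["chrom", "start"], kind="mergesort"
    ).reset_index(drop=True)

    truth = GroundTruth(
        base_freqs_chip=base_chip,
        base_freqs_seq=base_seq,
        pop_freqs_chip=pop_freqs_chip,
        pop_freqs_seq=pop_freqs_seq,
        true_f=true_f,
        implanted_roh=implanted,
        fixed_differences=truth_fd,
        enriched_snps=enriched,
        ancestral_is_alt=ancestral_is_alt,
    )
    return SimulatedStudy(cfg, chip, variant_tables, tracks, outgroup, qtls, genes, truth)


def _true_fixed_differences(
    cfg: SimConfig,
    sample_ids: list[str],
    populations: dict[str, str],
    seq_map: pd.DataFrame,
    seq_calls: np.ndarray,
    variant_tables: dict[str, VariantTable],
    nonsyn_mask: np.ndarray,
    local_breeds: list[str],
    commercial_ids: list[str],
    ancestral_is_alt: np.ndarray,
) -> pd.DataFrame:
    """Apply the screen's defining rules directly to the generator state.

    Uses the *emitted* genotypes after depth masking and after the
    study's SNP-quality floor (quality < 20 counts as missing, matching
    the variant QC a correct pipeline applies), so loci that pass or
    fail by chance are part of the truth, not only the implants.
    """
    cols = [
        "chrom", "pos", "local_breed", "commercial_allele", "local_allele",
        "ancestral_allele", "derived_fixed_in",
    ]
    if not commercial_ids or not local_breeds:
        return pd.DataFrame(columns=cols)
    emitted = {}
    for sid, vt in variant_tables.items():
        gen = vt.records["genotype"].to_numpy().copy()
        gen[vt.records["snp_quality"].to_numpy() < 20.0] = MISSING
        emitted[sid] = gen
    rows = []
    nonsyn_idx = np.nonzero(nonsyn_mask)[0]
    comm = np.vstack([emitted[s] for s in commercial_ids])
    for breed in local_breeds:
        breed_ids = [s for s in variant_tables if populations[s] == breed][:2]
        if len(breed_ids) < 2:
            continue
        loc = np.vstack([emitted[s] for s in breed_ids])
        for i in nonsyn_idx:
            cg = comm[:, i]
            typed = cg != MISSING
            if (len(cg) - typed.sum()) > 3 or typed.sum() == 0:
                continue
            vals = np.unique(cg[typed])
            if len(vals) != 1 or vals[0] == 1:
                continue
            lg = loc[:, i]
            if (lg == MISSING).any():
                continue
            lvals = np.unique(lg)
            if len(lvals) != 1 or lvals[0] == 1 or lvals[0] == vals[0]:
                continue
            ref, alt = seq_map["ref"].iat[i], seq_map["alt"].iat[i]
            comm_allele = ref if vals[0] == 0 else alt
            local_allele = ref if lvals[0] == 0 else alt
            anc = alt if ancestral_is_alt[i] else ref
            derived_in = "local" if anc == comm_allele else "commercial"
            rows.append(
                (
                    seq_map["chrom"].iat[i],
                    int(seq_map["pos"].iat[i]),
                    breed,
                    comm_allele,
                    local_allele,
                    anc,
                    derived_in,
                )
            )
    return pd.DataFrame(rows, columns=cols)
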