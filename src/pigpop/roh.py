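"""Runs of homozygosity, called two ways.

Chip caller: maximal stretches of chip markers that are homozygous in
the individual, tolerating one heterozygous call in total, supported by
at least 20 homozygous SNPs, spanning at least 10 kb, with no gap
between consecutive markers above 1 Mb and at least 1 supporting SNP
per Mb.  Segment endpoints are the outermost supporting (homozygous)
markers.  Note that with the default parameters the density constraint
is implied by the gap constraint (n SNPs with all gaps <= 1 Mb span at
most (n-1) Mb); it is still checked so non-default configurations
behave as documented.  Maximal qualifying segments on either side of a
two-het break are both reported (they overlap between the two hets);
genome-fraction summaries count overlapping base pairs once.

Sequence caller (SNP-density rule): tile each chromosome into 100-kb
bins, count the individual's heterozygous SNPs per bin (configurable to
all variant sites), and extract maximal chains of consecutive bins
whose count is at most 0.25x the genomic bin average; a chain of at
least 10 bins whose mean count stays below the genomic average becomes
a ROH spanning the chain's bins.  Bins failing the callability floor
break chains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    MISSING,
    CallabilityTrack,
    GenotypeMatrix,
    ParameterError,
    PigpopError,
    RohInterval,
    RohSet,
    VariantTable,
)


# ---------------------------------------------------------------------------
# chip caller
# ---------------------------------------------------------------------------

def call_roh_chip(
    g: GenotypeMatrix,
    individual: str,
    min_snps: int = 20,
    max_het: int = 1,
    min_len: int = 10_000,
    min_density: float = 1.0 / 1_000_000,  # supporting SNPs per bp
    max_gap: int = 1_000_000,
) -> RohSet:
    """Call ROH from chip genotypes for one individual."""
    row = g.calls[g.sample_index(individual)]
    intervals: list[RohInterval] = []
    for chrom, sub in g.markers.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        geno = row[idx]
        intervals.extend(
            _chip_segments(chrom, pos, geno, individual, min_snps, max_het, min_len, min_density, max_gap)
        )
    return RohSet(_drop_contained(intervals))


def _chip_segments(
    chrom: str,
    pos: np.ndarray,
    geno: np.ndarray,
    individual: str,
    min_snps: int,
    max_het: int,
    min_len: int,
    min_density: float,
    max_gap: int,
) -> list[RohInterval]:
    out: list[RohInterval] = []
    if len(pos) == 0:
        return out
    # blocks: no gap between consecutive markers above max_gap
    breaks = np.nonzero(np.diff(pos) > max_gap)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(pos) - 1]])
    for blk_s, blk_e in zip(starts, ends):
        p = pos[blk_s : blk_e + 1]
        gblk = geno[blk_s : blk_e + 1]
        hets = np.nonzero(gblk == 1)[0]
        # maximal windows containing at most max_het heterozygous calls
        if len(hets) <= max_het:
            windows = [(0, len(gblk) - 1)]
        else:
            padded = np.concatenate([[-1], hets, [len(gblk)]])
            windows = [
                (padded[k] + 1, padded[k + max_het + 1] - 1)
                for k in range(len(hets) - max_het + 1)
            ]
        for a, b in windows:
            seg = _trim_to_hom(gblk, a, b)
            if seg is None:
                continue
            a2, b2 = seg
            hom = int(np.isin(gblk[a2 : b2 + 1], (0, 2)).sum())
            length = int(p[b2]) + 1 - int(p[a2])
            if hom < min_snps or length < min_len or hom / length < min_density:
                continue
            out.append(RohInterval(individual, chrom, int(p[a2]), int(p[b2]) + 1, hom, "chip"))
    return out


def _trim_to_hom(geno: np.ndarray, a: int, b: int) -> tuple[int, int] | None:
    while a <= b and geno[a] not in (0, 2):
        a += 1
    while b >= a and geno[b] not in (0, 2):
        b -= 1
    return (a, b) if a <= b else None


def _drop_contained(intervals: list[RohInterval]) -> list[RohInterval]:
    """Remove duplicates and intervals contained in a longer call."""
    uniq = sorted(set(intervals), key=lambda r: (r.chrom, r.start, -(r.end)))
    kept: list[RohInterval] = []
    last_end = {}
    for r in uniq:
        if r.chrom in last_end and r.end <= last_end[r.chrom]:
            continue  # contained in a previously kept interval
        kept.append(r)
        last_end[r.chrom] = r.end
    return kept


# ---------------------------------------------------------------------------
# sequence caller
# ---------------------------------------------------------------------------

def call_roh_ngs(
    v: VariantTable,
    track: CallabilityTrack,
    bin_bp: int = 100_000,
    density_fraction: float = 0.25,
    min_consecutive: int = 10,
    min_len: int = 10_000,
    min_callable_fraction: float = 0.2,
    density_counts: str = "het_only",
) -> RohSet:
    """Call ROH from the SNP-density-per-bin rule.

    ``density_counts='het_only'`` counts heterozygous SNPs (homozygous
    alternates are not evidence against autozygosity);
    ``'all_snps'`` counts every non-missing variant site.
    """
    if bin_bp % track.tile_bp:
        raise ParameterError(f"bin_bp must be a multiple of the {track.tile_bp}-bp tiles")
    if density_counts not in ("het_only", "all_snps"):
        raise ParameterError(f"unknown density_counts mode {density_counts!r}")
    snps = v.snps
    if density_counts == "het_only":
        snps = snps[snps["genotype"] == 1]
    else:
        snps = snps[snps["genotype"].isin((1, 2))]

    per_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    all_counts = []
    for chrom, length in track.chrom_lengths.items():
        n_bins = length // bin_bp
        if n_bins == 0:
            continue
        edges = np.arange(n_bins + 1) * bin_bp
        pos = snps.loc[snps["chrom"] == chrom, "pos"].to_numpy()
        counts = np.histogram(pos, bins=edges)[0]
        tiles_per_bin = bin_bp // track.tile_bp
        callable_per_bin = (
            track.counts[chrom][: n_bins * tiles_per_bin]
            .reshape(n_bins, tiles_per_bin)
            .sum(axis=1)
        )
        callable_ok = callable_per_bin >= min_callable_fraction * bin_bp
        per_chrom[chrom] = (counts, callable_ok)
        all_counts.append(counts[callable_ok])
    if not all_counts or not len(np.concatenate(all_counts)):
        raise PigpopError("no callable bins: cannot compute the genomic average")
    genomic_avg = float(np.concatenate(all_counts).mean())
    if genomic_avg == 0.0:
        raise PigpopError("genomic average SNP count per bin is zero (degenerate input)")

    intervals: list[RohInterval] = []
    threshold = density_fraction * genomic_avg
    for chrom, (counts, callable_ok) in per_chrom.items():
        qualifying = callable_ok & (counts <= threshold)
        # maximal chains of consecutive qualifying bins
        b = 0
        n_bins = len(counts)
        while b < n_bins:
            if not qualifying[b]:
                b += 1
                continue
            e = b
            while e + 1 < n_bins and qualifying[e + 1]:
                e += 1
            chain = counts[b : e + 1]
            n_chain = e - b + 1
            span = n_chain * bin_bp
            if (
                n_chain >= min_consecutive
                and chain.mean() < genomic_avg
                and span >= min_len
            ):
                intervals.append(
                    RohInterval(
                        v.individual_id,
                        chrom,
                        int(b * bin_bp),
                        int(min((e + 1) * bin_bp, track.chrom_lengths[chrom])),
                        int(chain.sum()),
                        "sequence",
                    )
                )
            b = e + 1
    return RohSet(intervals)


# ---------------------------------------------------------------------------
# summaries and comparison
# ---------------------------------------------------------------------------

def roh_genome_fraction(rohs: RohSet, genome_size: int) -> float:
    """Fraction of the genome covered by ROH (overlaps counted once)."""
    if genome_size <= 0:
        raise ParameterError("genome_size must be positive")
    return rohs.union_bp() / genome_size


def roh_summary(rohs: RohSet, genome_size: int) -> pd.DataFrame:
    """Per-individual ROH count, total bp and genome fraction."""
    rows = []
    for ind in sorted({r.individual for r in rohs}):
        sub = rohs.for_individual(ind)
        rows.append((ind, len(sub), sub.union_bp(), sub.union_bp() / genome_size))
    return pd.DataFrame(rows, columns=["individual", "n_roh", "total_bp", "fraction"])


def _merged(intervals: list[tuple[str, int, int]]) -> dict[str, list[tuple[int, int]]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in intervals:
        by_chrom.setdefault(chrom, []).append((s, e))
    out = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        merged = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        out[chrom] = merged
    return out


def _overlap_bp(a: dict[str, list[tuple[int, int]]], b: dict[str, list[tuple[int, int]]]) -> int:
    total = 0
    for chrom in set(a) & set(b):
        i = j = 0
        ia, ib = a[chrom], b[chrom]
        while i < len(ia) and j < len(ib):
            s = max(ia[i][0], ib[j][0])
            e = min(ia[i][1], ib[j][1])
            if e > s:
                total += e - s
            if ia[i][1] <= ib[j][1]:
                i += 1
            else:
                j += 1
    return total


def interval_jaccard(
    a: list[tuple[str, int, int]], b: list[tuple[str, int, int]]
) -> float:
    """Base-pair Jaccard index between two interval collections."""
    ma, mb = _merged(a), _merged(b)
    inter = _overlap_bp(ma, mb)
    bp = lambda m: sum(e - s for ivs in m.values() for s, e in ivs)
    union = bp(ma) + bp(mb) - inter
    return inter / union if union else float("nan")


def _as_tuples(rohs: RohSet) -> list[tuple[str, int, int]]:
    return [(r.chrom, r.start, r.end) for r in rohs]


def detection_rate(
    reference: list[tuple[str, int, int]],
    calls: RohSet,
    min_overlap_fraction: float = 0.5,
) -> float:
    """Fraction of reference intervals with at least
    ``min_overlap_fraction`` of their length covered by calls."""
    if not reference:
        return float("nan")
    called = _merged(_as_tuples(calls))
    hits = 0
    for chrom, s, e in reference:
        cov = _overlap_bp({chrom: [(s, e)]}, called)
        if cov >= min_overlap_fraction * (e - s):
            hits += 1
    return hits / len(reference)


def compare_roh(
    r_chip: RohSet,
    r_seq: RohSet,
    genome_size: int,
    length_split_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Per-individual chip-vs-sequence comparison.

    Reports the bp Jaccard between the two call sets, the genome
    fraction covered by each, and, taking the sequence calls as the
    reference, the fraction of short (< split) and long (>= split)
    sequence ROH that the chip caller recovers.
    """
    inds = sorted({r.individual for r in r_chip} | {r.individual for r in r_seq})
    rows = []
    for ind in inds:
        chip = r_chip.for_individual(ind)
        seq = r_seq.for_individual(ind)
        seq_short = [(r.chrom, r.start, r.end) for r in seq if r.length < length_split_bp]
        seq_long = [(r.chrom, r.start, r.end) for r in seq if r.length >= length_split_bp]
        rows.append(
            (
                ind,
                interval_jaccard(_as_tuples(chip), _as_tuples(seq)),
                chip.union_bp() / genome_size,
                seq.union_bp() / genome_size,
                detection_rate(seq_short, chip),
                detection_rate(seq_long, chip),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "individual",
            "jaccard",
            "chip_fraction",
            "seq_fraction",
            "short_detected_by_chip",
            "long_detected_by_chip",
        ],
    )
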