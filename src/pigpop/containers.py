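"""In-memory containers shared by every pipeline stage.

Conventions used throughout the package:

* Genotypes are diploid biallelic codes counting alternate alleles:
  ``0`` hom-ref, ``1`` het, ``2`` hom-alt, ``-1`` missing.
* All positions and intervals are 0-based internally; intervals are
  half-open ``[start, end)``.  File writers emit 1-based SNP positions
  (VCF/TSV convention) and 0-based half-open intervals (BED convention).
* Only the 18 pig autosomes (or the synthetic chromosomes standing in
  for them) are ever present; sex chromosomes are dropped on ingest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1  # genotype sentinel

MARKER_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]
VARIANT_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "genotype",
    "depth",
    "snp_quality",
    "variant_type",
    "functional_class",
    "damage_label",
]


class PigpopError(Exception):
    """Base class for pipeline errors."""


def natural_chrom_key(chrom: str) -> tuple[int, str]:
    """Sort key placing numeric chromosome names in numeric order."""
    s = str(chrom)
    return (int(s), "") if s.isdigit() else (10**9, s)


class ParameterError(PigpopError):
    """A caller supplied an out-of-range or inconsistent parameter."""


class ParseError(PigpopError):
    """A file could not be interpreted; the message names the offending line."""


@dataclass
class GenotypeMatrix:
    """Chip-style genotype matrix: samples x biallelic autosomal SNPs.

    Parameters
    ----------
    sample_ids
        Ordered sample names; rows of ``calls``.
    populations
        Mapping sample id -> population label.
    markers
        Marker map with columns ``chrom, pos, id, ref, alt``, sorted by
        (chrom, pos) with unique positions per chromosome.
    calls
        ``int8`` array of shape (n_samples, n_markers).
    """

    sample_ids: list[str]
    populations: dict[str, str]
    markers: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.markers = self.markers.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.validate()

    # -- structure ---------------------------------------------------------
    def validate(self) -> None:
        if list(self.markers.columns[:5]) != MARKER_COLUMNS:
            raise ParameterError(
                f"marker table must have columns {MARKER_COLUMNS}, "
                f"got {list(self.markers.columns)}"
            )
        if self.calls.shape != (len(self.sample_ids), len(self.markers)):
            raise ParameterError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.markers)} markers"
            )
        by_chrom = self.markers.groupby("chrom", sort=False)["pos"]
        if not by_chrom.apply(lambda p: p.is_monotonic_increasing and p.is_unique).all():
            raise ParameterError("markers must be sorted with unique positions per chromosome")
        valid = np.isin(self.calls, (MISSING, 0, 1, 2))
        if not valid.all():
            raise ParameterError("genotype codes must be in {-1, 0, 1, 2}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def sample_index(self, sample: str) -> int:
        try:
            return self.sample_ids.index(sample)
        except ValueError:
            raise ParameterError(f"unknown sample {sample!r}") from None

    def population_of(self, sample: str) -> str:
        return self.populations[sample]

    def population_samples(self, population: str) -> list[str]:
        return [s for s in self.sample_ids if self.populations.get(s) == population]

    def population_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.populations.get(s, ""), None)
        return [p for p in seen if p]

    # -- views -------------------------------------------------------------
    def subset_samples(self, samples: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(s) for s in samples]
        return GenotypeMatrix(
            sample_ids=list(samples),
            populations={s: self.populations[s] for s in samples},
            markers=self.markers.copy(),
            calls=self.calls[idx, :].copy(),
        )

    def subset_markers(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            populations=dict(self.populations),
            markers=self.markers.loc[mask].reset_index(drop=True),
            calls=self.calls[:, mask].copy(),
        )

    def calls_for(self, sample: str) -> np.ndarray:
        return self.calls[self.sample_index(sample)]

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.populations == other.populations
            and self.markers[MARKER_COLUMNS].equals(other.markers[MARKER_COLUMNS])
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class VariantTable:
    """One individual's sequence-derived variant calls.

    ``records`` columns: ``chrom, pos, ref, alt, genotype, depth,
    snp_quality, variant_type, functional_class, damage_label`` with
    ``variant_type`` in {"snp", "indel"}, ``functional_class`` in
    {"synonymous", "non-synonymous", "other"} and ``damage_label`` in
    {"benign", "possibly_damaging", "probably_damaging", "none"}.
    """

    individual_id: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing_cols = [c for c in VARIANT_COLUMNS if c not in self.records.columns]
        if missing_cols:
            raise ParameterError(f"variant table missing columns {missing_cols}")
        key = self.records["chrom"].map(natural_chrom_key)
        self.records = (
            self.records.assign(_ck=key)
            .sort_values(["_ck", "pos"], kind="mergesort")
            .drop(columns="_ck")
            .reset_index(drop=True)
        )
        if (self.records["depth"] < 0).any():
            raise ParameterError("depth must be non-negative")

    @property
    def snps(self) -> pd.DataFrame:
        return self.records[self.records["variant_type"] == "snp"]

    def nonsynonymous(self) -> pd.DataFrame:
        snps = self.snps
        return snps[snps["functional_class"] == "non-synonymous"]


@dataclass
class CallabilityTrack:
    """Callable-site counts per fixed-size tile, one array per chromosome.

    A site is callable when its depth lies in the configured window
    (floor .. ceiling).  Tiles are ``tile_bp`` wide; the last tile of a
    chromosome may be shorter.  Queries must be tile-aligned, which all
    pipeline bin sizes (multiples of ``tile_bp``) guarantee.
    """

    tile_bp: int
    chrom_lengths: dict[str, int]
    counts: dict[str, np.ndarray]
    mean_depth: float = float("nan")

    def n_tiles(self, chrom: str) -> int:
        return len(self.counts[chrom])

    def callable_in(self, chrom: str, start: int, end: int) -> int:
        if start % self.tile_bp or (end % self.tile_bp and end < self.chrom_lengths[chrom]):
            raise ParameterError(
                f"query [{start},{end}) not aligned to {self.tile_bp}-bp tiles"
            )
        arr = self.counts[chrom]
        return int(arr[start // self.tile_bp : -(-end // self.tile_bp)].sum())

    def total_callable(self) -> int:
        return int(sum(int(a.sum()) for a in self.counts.values()))

    def genome_size(self) -> int:
        return int(sum(self.chrom_lengths.values()))


@dataclass(frozen=True)
class RohInterval:
    """A called run of homozygosity (half-open interval)."""

    individual: str
    chrom: str
    start: int
    end: int
    n_snps: int
    source: str  # "chip" | "sequence"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ParameterError(f"ROH end {self.end} <= start {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RohSet:
    """A collection of ROH calls, usually per individual and source."""

    intervals: list[RohInterval] = field(default_factory=list)

    def __iter__(self) -> Iterator[RohInterval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def for_individual(self, individual: str) -> "RohSet":
        return RohSet([r for r in self.intervals if r.individual == individual])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.individual, r.chrom, r.start, r.end, r.n_snps, r.source)
                for r in sorted(
                    self.intervals, key=lambda r: (r.individual, r.chrom, r.start, r.end)
                )
            ],
            columns=["individual", "chrom", "start", "end", "n_snps", "source"],
        )

    def union_bp(self) -> int:
        """Total base pairs covered, counting overlapping calls once."""
        total = 0
        by_key: dict[tuple[str, str], list[RohInterval]] = {}
        for r in self.intervals:
            by_key.setdefault((r.individual, r.chrom), []).append(r)
        for group in by_key.values():
            group.sort(key=lambda r: r.start)
            cur_s, cur_e = None, None
            for r in group:
                if cur_e is None or r.start > cur_e:
                    if cur_e is not None:
                        total += cur_e - cur_s
                    cur_s, cur_e = r.start, r.end
                else:
                    cur_e = max(cur_e, r.end)
            if cur_e is not None:
                total += cur_e - cur_s
        return total


@dataclass
class QTLSet:
    """Published QTL intervals with phenotype-category labels."""

    intervals: pd.DataFrame  # chrom, start, end, category, name

    def __post_init__(self) -> None:
        required = ["chrom", "start", "end", "category", "name"]
        missing = [c for c in required if c not in self.intervals.columns]
        if missing:
            raise ParameterError(f"QTL table missing columns {missing}")
        bad = self.intervals["start"] >= self.intervals["end"]
        if bad.any():
            row = self.intervals[bad].iloc[0]
            raise ParseError(
                f"QTL interval start >= end at {row['chrom']}:{row['start']}-{row['end']}"
            )
        self.intervals = self.intervals.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.intervals)

    def categories(self) -> list[str]:
        return sorted(self.intervals["category"].unique())

    def category(self, name: str) -> pd.DataFrame:
        return self.intervals[self.intervals["category"] == name]


@dataclass(frozen=True)
class FixedDifferenceRecord:
    """A non-synonymous SNP fixed for different alleles in a local breed
    versus the pooled commercial population."""

    chrom: str
    pos: int
    ref: str
    alt: str
    local_breed: str
    commercial_allele: str
    local_allele: str
    n_local_hom: int
    n_commercial_typed: int
    gene: str = "none"
    damage_label: str = "none"
    ancestral_allele: str = "unknown"  # commercial/local allele base, or "unknown"
    derived_fixed_in: str = "unknown"  # "local" | "commercial" | "unknown"

    def __post_init__(self) -> None:
        if self.commercial_allele == self.local_allele:
            raise ParameterError("fixed difference requires distinct alleles")


@dataclass
class OverlapTestResult:
    """Permutation test outcome for one QTL category."""

    category: str
    observed_overlap: int
    null_counts: np.ndarray
    p_value: float
    n_perm: int
    seed: int | None
    exact: bool = False
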