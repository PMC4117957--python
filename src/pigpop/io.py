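"""Readers, writers and QC filters for the standard file formats.

Chip genotypes travel as VCF or a wide TSV (marker map + one column per
sample); per-individual sequence variants as VCF or TSV; QTLs and ROH as
BED.  Positions are converted between the 1-based VCF/TSV convention on
disk and the package's internal 0-based coordinates on ingest/emit;
BED intervals are 0-based half-open on both sides.

The two QC filters implement the study's marker and variant rules:
chip markers must map to an autosome and show <5% missing genotypes;
sequence SNPs need genotype quality >= 20 (INDELs >= 50) and depth
between 5x and twice the genome-wide average.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import (
    MARKER_COLUMNS,
    MISSING,
    VARIANT_COLUMNS,
    CallabilityTrack,
    GenotypeMatrix,
    ParameterError,
    ParseError,
    QTLSet,
    RohSet,
    VariantTable,
)

logger = logging.getLogger(__name__)

_GT_TO_VCF = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


# ---------------------------------------------------------------------------
# populations
# ---------------------------------------------------------------------------

def read_populations(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (sample, population) into a mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected columns sample, population")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_populations(populations: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"sample": list(populations), "population": list(populations.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotype matrix
# ---------------------------------------------------------------------------

def read_genotype_matrix(
    path: str | Path,
    format: str | None = None,
    populations: Mapping[str, str] | str | Path | None = None,
) -> GenotypeMatrix:
    """Read a genotype matrix from VCF or TSV.

    Multi-allelic sites and non-SNP records are dropped (count logged).
    ``populations`` maps samples to breed labels; a path is read as a
    populations TSV; omitted, every sample is labelled ``"all"``.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix == ".vcf" or path.name.endswith(".vcf.gz") else "tsv"
    if isinstance(populations, (str, Path)):
        populations = read_populations(populations)
    if format == "vcf":
        return _read_genotype_vcf(path, populations)
    if format == "tsv":
        return _read_genotype_tsv(path, populations)
    raise ParameterError(f"unknown genotype format {format!r}")


def _pop_map(sample_ids: Sequence[str], populations: Mapping[str, str] | None) -> dict[str, str]:
    if populations is None:
        return {s: "all" for s in sample_ids}
    missing = [s for s in sample_ids if s not in populations]
    if missing:
        raise ParameterError(f"samples without population label: {missing}")
    return {s: populations[s] for s in sample_ids}


def _read_genotype_vcf(path: Path, populations: Mapping[str, str] | None) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rows, genos = [], []
    n_multiallelic = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multiallelic += 1
            continue
        # cyvcf2 gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = v.gt_types.astype(np.int8)
        codes = np.where(gt == 3, 2, np.where(gt == 2, MISSING, gt))
        rows.append((v.CHROM, v.POS - 1, v.ID or f"{v.CHROM}_{v.POS}", v.REF, v.ALT[0]))
        genos.append(codes)
    vcf.close()
    if n_multiallelic:
        logger.info("dropped %d multi-allelic site(s) from %s", n_multiallelic, path)
    markers = pd.DataFrame(rows, columns=MARKER_COLUMNS)
    calls = (
        np.array(genos, dtype=np.int8).T
        if genos
        else np.empty((len(sample_ids), 0), dtype=np.int8)
    )
    # record order is preserved; an unsorted VCF fails matrix validation
    return GenotypeMatrix(sample_ids, _pop_map(sample_ids, populations), markers, calls)


def _read_genotype_tsv(path: Path, populations: Mapping[str, str] | None) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: {exc}") from exc
    missing_cols = [c for c in MARKER_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ParseError(f"{path}: missing marker columns {missing_cols}")
    sample_ids = [c for c in df.columns if c not in MARKER_COLUMNS]
    markers = df[MARKER_COLUMNS].copy()
    markers["pos"] = markers["pos"].astype(int) - 1  # 1-based on disk
    calls = df[sample_ids].to_numpy(dtype=np.int8).T
    return GenotypeMatrix(sample_ids, _pop_map(sample_ids, populations), markers, calls)


def write_genotype_matrix(g: GenotypeMatrix, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix == ".vcf" else "tsv"
    if format == "vcf":
        _write_genotype_vcf(g, path)
    elif format == "tsv":
        df = g.markers.copy()
        df["pos"] = df["pos"] + 1
        for i, s in enumerate(g.sample_ids):
            df[s] = g.calls[i]
        df.to_csv(path, sep="\t", index=False)
    else:
        raise ParameterError(f"unknown genotype format {format!r}")


def _write_genotype_vcf(g: GenotypeMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, sub in g.markers.groupby("chrom", sort=False):
            fh.write(f"##contig=<ID={chrom},length={int(sub['pos'].max()) + 2}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.sample_ids)
            + "\n"
        )
        for j, row in enumerate(g.markers.itertuples(index=False)):
            gts = "\t".join(_GT_TO_VCF[int(c)] for c in g.calls[:, j])
            fh.write(
                f"{row.chrom}\t{row.pos + 1}\t{row.id}\t{row.ref}\t{row.alt}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# variant tables
# ---------------------------------------------------------------------------

def read_variant_table(path: str | Path, individual_id: str | None = None, format: str | None = None) -> VariantTable:
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix == ".vcf" or path.name.endswith(".vcf.gz") else "tsv"
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        missing_cols = [c for c in VARIANT_COLUMNS if c not in df.columns]
        if missing_cols:
            raise ParseError(f"{path}: missing variant columns {missing_cols}")
        df = df[VARIANT_COLUMNS].copy()
        df["pos"] = df["pos"].astype(int) - 1
        return VariantTable(individual_id or path.stem, df)
    if format == "vcf":
        return _read_variant_vcf(path, individual_id)
    raise ParameterError(f"unknown variant format {format!r}")


def _read_variant_vcf(path: Path, individual_id: str | None) -> VariantTable:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample = individual_id or (vcf.samples[0] if vcf.samples else path.stem)
    rows = []
    for v in vcf:
        if len(v.ALT) != 1:
            continue
        gt = int(v.gt_types[0])
        code = 2 if gt == 3 else (MISSING if gt == 2 else gt)
        depth = int(v.gt_depths[0]) if v.gt_depths is not None and v.gt_depths[0] >= 0 else 0
        rows.append(
            (
                v.CHROM,
                v.POS - 1,
                v.REF,
                v.ALT[0],
                code,
                depth,
                float(v.QUAL) if v.QUAL is not None else 0.0,
                v.INFO.get("VT", "snp"),
                v.INFO.get("FC", "other"),
                v.INFO.get("DMG", "none"),
            )
        )
    vcf.close()
    return VariantTable(sample, pd.DataFrame(rows, columns=VARIANT_COLUMNS))


def write_variant_table(v: VariantTable, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix == ".vcf" else "tsv"
    if format == "tsv":
        df = v.records.copy()
        df["pos"] = df["pos"] + 1
        df.to_csv(path, sep="\t", index=False)
        return
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=VT,Number=1,Type=String,Description="Variant type">\n')
        fh.write('##INFO=<ID=FC,Number=1,Type=String,Description="Functional class">\n')
        fh.write('##INFO=<ID=DMG,Number=1,Type=String,Description="Damage label">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        for chrom, sub in v.records.groupby("chrom", sort=False):
            fh.write(f"##contig=<ID={chrom},length={int(sub['pos'].max()) + 2}>\n")
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{v.individual_id}\n")
        for r in v.records.itertuples(index=False):
            info = f"VT={r.variant_type};FC={r.functional_class};DMG={r.damage_label}"
            fh.write(
                f"{r.chrom}\t{r.pos + 1}\t.\t{r.ref}\t{r.alt}\t{r.snp_quality:g}\t.\t"
                f"{info}\tGT:DP\t{_GT_TO_VCF[int(r.genotype)]}:{int(r.depth)}\n"
            )


# ---------------------------------------------------------------------------
# callability tracks
# ---------------------------------------------------------------------------

def write_callability_track(track: CallabilityTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#tile_bp={track.tile_bp}\tmean_depth={track.mean_depth:g}\n")
        fh.write("chrom\ttile_start\tchrom_length\tcallable\n")
        for chrom, arr in track.counts.items():
            length = track.chrom_lengths[chrom]
            for i, c in enumerate(arr):
                fh.write(f"{chrom}\t{i * track.tile_bp}\t{length}\t{int(c)}\n")


def read_callability_track(path: str | Path) -> CallabilityTrack:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#tile_bp="):
            raise ParseError(f"{path}: missing tile header line")
        fields = dict(part.split("=") for part in header.lstrip("#").split("\t"))
        df = pd.read_csv(fh, sep="\t", dtype={"chrom": str})
    tile_bp = int(fields["tile_bp"])
    counts, lengths = {}, {}
    for chrom, sub in df.groupby("chrom", sort=False):
        counts[chrom] = sub["callable"].to_numpy(dtype=np.int64)
        lengths[chrom] = int(sub["chrom_length"].iloc[0])
    return CallabilityTrack(tile_bp, lengths, counts, float(fields["mean_depth"]))


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------

def filter_chip_markers(
    g: GenotypeMatrix,
    max_missing: float = 0.05,
    autosomes: Iterable[str] | None = None,
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Apply the chip marker QC: autosomal markers with <``max_missing``
    fraction of missing genotypes.

    Returns the filtered matrix and per-criterion removal counts.
    ``autosomes=None`` accepts every chromosome present (synthetic
    genomes are all-autosomal by construction).
    """
    if not 0.0 <= max_missing <= 1.0:
        raise ParameterError("max_missing must lie in [0, 1]")
    n_input = g.n_markers
    if autosomes is not None:
        autosomal = g.markers["chrom"].isin(set(autosomes)).to_numpy()
    else:
        autosomal = np.ones(n_input, dtype=bool)
    miss_frac = (g.calls == MISSING).mean(axis=0) if g.n_samples else np.zeros(n_input)
    low_missing = miss_frac < max_missing
    keep = autosomal & low_missing
    report = {
        "n_input": n_input,
        "removed_non_autosomal": int((~autosomal).sum()),
        "removed_missing": int((autosomal & ~low_missing).sum()),
        "n_retained": int(keep.sum()),
    }
    if report["n_retained"] == 0:
        warnings.warn("no markers passed chip QC", stacklevel=2)
    logger.info("chip QC: %s", report)
    return g.subset_markers(keep), report


def filter_variant_calls(
    v: VariantTable,
    genome_mean_depth: float,
    snp_quality_min: float = 20.0,
    indel_quality_min: float = 50.0,
    depth_floor: int = 5,
) -> tuple[VariantTable, dict[str, int]]:
    """Apply the sequence-variant QC: SNP quality >= 20 (INDEL >= 50) and
    per-site depth between ``depth_floor`` and twice the genome average.

    INDELs that pass stay in the table flagged by ``variant_type`` so
    SNP-only stages (via ``VariantTable.snps``) never see them.
    """
    if genome_mean_depth <= 0:
        raise ParameterError("genome_mean_depth must be positive")
    rec = v.records
    is_snp = rec["variant_type"] == "snp"
    qual_ok = np.where(is_snp, rec["snp_quality"] >= snp_quality_min, rec["snp_quality"] >= indel_quality_min)
    depth_ok = (rec["depth"] >= depth_floor) & (rec["depth"] <= 2.0 * genome_mean_depth)
    keep = qual_ok & depth_ok
    report = {
        "n_input": len(rec),
        "removed_quality": int((~qual_ok).sum()),
        "removed_depth": int((qual_ok & ~depth_ok).sum()),
        "n_retained": int(keep.sum()),
    }
    logger.info("variant QC for %s: %s", v.individual_id, report)
    return VariantTable(v.individual_id, rec[keep].reset_index(drop=True)), report


# ---------------------------------------------------------------------------
# BED: QTLs and ROH
# ---------------------------------------------------------------------------

def _category_from_name(name: str) -> str:
    return name[4:] if name.startswith("QTL_") else name


def read_qtl_bed(path: str | Path) -> QTLSet:
    """Read QTL intervals from BED (0-based half-open).

    Column 4 is the QTL name; an optional non-numeric column 5 is the
    phenotype category, otherwise the category is the name with any
    ``QTL_`` prefix stripped.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start {start} >= end {end}")
            name = parts[3] if len(parts) > 3 else f"qtl_{lineno}"
            category = _category_from_name(name)
            if len(parts) > 4:
                try:
                    float(parts[4])  # a numeric col 5 is a BED score, not a category
                except ValueError:
                    category = parts[4]
            rows.append((chrom, start, end, category, name))
    return QTLSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "category", "name"]))


def write_qtl_bed(qtls: QTLSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in qtls.intervals.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.category}\n")


def write_roh_bed(rohs: RohSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in rohs.to_frame().itertuples(index=False):
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.individual}|{r.source}\t{r.n_snps}\n"
            )


def read_roh_bed(path: str | Path) -> RohSet:
    from .containers import RohInterval

    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 5 or "|" not in parts[3]:
                raise ParseError(f"{path}:{lineno}: not a pigpop ROH BED line")
            individual, source = parts[3].split("|", 1)
            intervals.append(
                RohInterval(individual, parts[0], int(parts[1]), int(parts[2]), int(parts[4]), source)
            )
    return RohSet(intervals)
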