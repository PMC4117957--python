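"""End-to-end orchestration: inputs -> diversity, ROH, FST, screen, overlap.

``PipelineConfig`` carries every stage threshold (defaulting to the
study's stated values) plus input paths and a single seed; it
round-trips to JSON.  ``run_pipeline`` executes the stages in order and
writes a report bundle: the per-breed diversity table, ROH BEDs and
fraction summaries for both callers, the pairwise-FST matrix and
Newick tree, the fixed-difference table, the per-category overlap test
and a run log with versions, seed, thresholds and every filter's
removal counts.  ``run_demo`` first materialises a synthetic study on
disk and then runs the same pipeline over those files, so the demo
exercises the io layer end to end.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, diversity, fst, io as pio, overlap, roh, screen
from .containers import PigpopError, RohSet
from .synthetic import SimConfig, SimulatedStudy, simulate_study

logger = logging.getLogger(__name__)


class StageError(PigpopError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Paths plus every tunable threshold of the pipeline."""

    # inputs
    genotypes: str = ""
    populations: str = ""
    variants_dir: str = ""
    tracks_dir: str = ""
    outgroup: str = ""
    qtls: str = ""
    genes: str = ""
    groups: str = ""  # TSV: breed <tab> individual (local breeds only)
    commercial: str = ""  # text file: one commercial individual per line
    out_dir: str = "pigpop_out"
    # marker QC
    max_missing: float = 0.05
    autosomes: list[str] | None = None
    # variant QC
    snp_quality_min: float = 20.0
    indel_quality_min: float = 50.0
    depth_floor: int = 5
    # binned heterozygosity
    het_bin_bp: int = 50_000
    het_depth_floor: int = 7
    min_callable_fraction: float = 0.2
    # chip ROH
    roh_min_snps: int = 20
    roh_max_het: int = 1
    roh_min_len: int = 10_000
    roh_min_density: float = 1.0 / 1_000_000
    roh_max_gap: int = 1_000_000
    # sequence ROH
    ngs_roh_bin_bp: int = 100_000
    ngs_density_fraction: float = 0.25
    ngs_min_consecutive: int = 10
    # screen
    max_commercial_missing: int = 3
    # overlap test
    n_perm: int = 1000
    tree_method: str = "upgma"
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


def read_groups(path: str | Path) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        breed, ind = line.split("\t")[:2]
        groups.setdefault(breed, []).append(ind)
    return groups


def write_study_inputs(study: SimulatedStudy, in_dir: str | Path) -> PipelineConfig:
    """Write a simulated study to disk in the pipeline's input formats
    and return a config pointing at the files."""
    in_dir = Path(in_dir)
    (in_dir / "variants").mkdir(parents=True, exist_ok=True)
    (in_dir / "tracks").mkdir(exist_ok=True)
    pio.write_genotype_matrix(study.chip, in_dir / "chip.tsv")
    pio.write_populations(study.chip.populations, in_dir / "populations.tsv")
    for sid, vt in study.variant_tables.items():
        pio.write_variant_table(vt, in_dir / "variants" / f"{sid}.tsv")
        pio.write_callability_track(study.tracks[sid], in_dir / "tracks" / f"{sid}.tsv")
    pio.write_variant_table(study.outgroup, in_dir / "outgroup.tsv")
    pio.write_qtl_bed(study.qtls, in_dir / "qtls.bed")
    with open(in_dir / "genes.bed", "w") as fh:
        for r in study.genes.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\n")
    local, commercial = study.groups()
    with open(in_dir / "groups.tsv", "w") as fh:
        for breed, members in local.items():
            for m in members:
                fh.write(f"{breed}\t{m}\n")
    (in_dir / "commercial.txt").write_text("".join(f"{s}\n" for s in commercial))
    return PipelineConfig(
        genotypes=str(in_dir / "chip.tsv"),
        populations=str(in_dir / "populations.tsv"),
        variants_dir=str(in_dir / "variants"),
        tracks_dir=str(in_dir / "tracks"),
        outgroup=str(in_dir / "outgroup.tsv"),
        qtls=str(in_dir / "qtls.bed"),
        genes=str(in_dir / "genes.bed"),
        groups=str(in_dir / "groups.tsv"),
        commercial=str(in_dir / "commercial.txt"),
    )


def _read_gene_bed(path: str | Path) -> pd.DataFrame:
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        rows.append((parts[0], int(parts[1]), int(parts[2]), parts[3] if len(parts) > 3 else "gene"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; returns a bundle of in-memory results and writes
    the report files under ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "pigpop_version": __version__,
        "seed": cfg.seed,
        "thresholds": dataclasses.asdict(cfg),
        "filters": {},
    }
    bundle: dict = {}

    def stage(name):
        def deco(fn):
            try:
                logger.info("stage %s", name)
                fn()
            except Exception as exc:
                raise StageError(name, exc) from exc

        return deco

    @stage("io-qc")
    def _io():
        g = pio.read_genotype_matrix(cfg.genotypes, populations=cfg.populations)
        g, report = pio.filter_chip_markers(g, cfg.max_missing, cfg.autosomes)
        log["filters"]["chip"] = report
        tables, tracks, reports = {}, {}, {}
        for path in sorted(Path(cfg.variants_dir).iterdir()):
            vt = pio.read_variant_table(path)
            track = pio.read_callability_track(Path(cfg.tracks_dir) / path.name)
            vt, rep = pio.filter_variant_calls(
                vt, track.mean_depth, cfg.snp_quality_min, cfg.indel_quality_min, cfg.depth_floor
            )
            tables[vt.individual_id] = vt
            tracks[vt.individual_id] = track
            reports[vt.individual_id] = rep
        log["filters"]["variants"] = reports
        bundle.update(genotypes=g, variant_tables=tables, tracks=tracks)
        bundle["genome_size"] = next(iter(tracks.values())).genome_size() if tracks else 0

    @stage("diversity")
    def _div():
        summary = diversity.diversity_summary(
            bundle["genotypes"],
            bundle["variant_tables"],
            bundle["tracks"],
            cfg.het_bin_bp,
            cfg.het_depth_floor,
            cfg.min_callable_fraction,
        )
        conc = diversity.concordance(summary)
        summary.per_population.to_csv(out / "diversity_by_population.tsv", sep="\t", index=False)
        summary.per_individual.to_csv(out / "diversity_by_individual.tsv", sep="\t", index=False)
        conc.to_csv(out / "concordance.tsv", sep="\t", index=False)
        bundle.update(diversity=summary, concordance=conc)

    @stage("roh")
    def _roh():
        g = bundle["genotypes"]
        chip_calls = RohSet(
            [
                r
                for s in g.sample_ids
                for r in roh.call_roh_chip(
                    g, s, cfg.roh_min_snps, cfg.roh_max_het, cfg.roh_min_len,
                    cfg.roh_min_density, cfg.roh_max_gap,
                )
            ]
        )
        seq_calls = RohSet(
            [
                r
                for sid, vt in bundle["variant_tables"].items()
                for r in roh.call_roh_ngs(
                    vt, bundle["tracks"][sid], cfg.ngs_roh_bin_bp, cfg.ngs_density_fraction,
                    cfg.ngs_min_consecutive, cfg.roh_min_len, cfg.min_callable_fraction,
                )
            ]
        )
        pio.write_roh_bed(chip_calls, out / "roh_chip.bed")
        pio.write_roh_bed(seq_calls, out / "roh_seq.bed")
        gs = bundle["genome_size"]
        roh.roh_summary(chip_calls, gs).to_csv(out / "roh_chip_summary.tsv", sep="\t", index=False)
        roh.roh_summary(seq_calls, gs).to_csv(out / "roh_seq_summary.tsv", sep="\t", index=False)
        comparison = roh.compare_roh(chip_calls, seq_calls, gs)
        comparison.to_csv(out / "roh_comparison.tsv", sep="\t", index=False)
        bundle.update(roh_chip=chip_calls, roh_seq=seq_calls, roh_comparison=comparison)

    @stage("fst")
    def _fst():
        m = fst.fst_matrix(bundle["genotypes"])
        m.to_csv(out / "fst_matrix.tsv", sep="\t")
        tree = fst.fst_dendrogram(m, cfg.tree_method)
        (out / "fst_tree.nwk").write_text(tree + "\n")
        bundle.update(fst_matrix=m, fst_tree=tree)

    @stage("screen")
    def _screen():
        groups = read_groups(cfg.groups)
        commercial = [
            s for s in Path(cfg.commercial).read_text().splitlines() if s.strip()
        ]
        genes = _read_gene_bed(cfg.genes) if cfg.genes else None
        records = screen.screen_fixed_differences(
            bundle["variant_tables"], groups, commercial, cfg.max_commercial_missing, genes
        )
        outgroup = pio.read_variant_table(cfg.outgroup, "Warthog")
        records = screen.polarize(records, outgroup)
        screen.records_to_frame(records).to_csv(out / "fixed_differences.tsv", sep="\t", index=False)
        summary = screen.summarize_screen(records)
        (out / "screen_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
        bundle.update(screen_records=records, screen_summary=summary)

    @stage("qtl-overlap")
    def _overlap():
        qtls = pio.read_qtl_bed(cfg.qtls)
        pool = sorted(
            {
                (r.chrom, int(r.pos))
                for vt in bundle["variant_tables"].values()
                for r in vt.nonsynonymous().itertuples(index=False)
            }
        )
        screened = sorted({(r.chrom, r.pos) for r in bundle["screen_records"]})
        table, results = overlap.test_all_categories(
            screened, pool, qtls, cfg.n_perm, cfg.seed
        )
        table.to_csv(out / "qtl_overlap.tsv", sep="\t", index=False)
        bundle.update(overlap_table=table, overlap_results=results)

    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str) + "\n")
    cfg.to_json(out / "config.json")
    return bundle


def run_demo(
    out_dir: str | Path,
    seed: int = 0,
    sim_config: SimConfig | None = None,
    n_perm: int = 1000,
) -> tuple[SimulatedStudy, dict]:
    """Simulate a study, write its inputs, and run the full pipeline.

    The sequence-ROH bin width is scaled to the toy genome (10 kb tiles
    against the 2 x 50 Mb default) so the bin rule keeps roughly the
    paper-scale resolution relative to genome size.
    """
    out_dir = Path(out_dir)
    cfg_sim = sim_config or SimConfig(seed=seed)
    study = simulate_study(cfg_sim, seed=seed)
    cfg = write_study_inputs(study, out_dir / "inputs")
    cfg.out_dir = str(out_dir / "results")
    cfg.seed = seed
    cfg.ngs_roh_bin_bp = cfg_sim.tile_bp
    cfg.n_perm = n_perm
    bundle = run_pipeline(cfg)
    return study, bundle
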