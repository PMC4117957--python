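"""Generate the synthetic study cohort and write every pipeline input.

Emulates the study design at toy-genome scale: a 2 x 50 Mb genome,
60K-density chip markers for twelve pigs (eight commercial, two local
breeds with two sequenced animals each), per-individual ~10x variant
tables with callability tracks, an outgroup genome, gene intervals and
four QTL categories (two enriched around the implanted fixed
differences, two null).  Ground-truth tables (true F, implanted ROH,
true fixed differences) are written alongside so later scripts can
score recovery.
"""

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SEED = 7

from pigpop.pipeline import write_study_inputs
from pigpop.synthetic import SimConfig, simulate_study


def main() -> None:
    cfg = SimConfig(seed=SEED)
    study = simulate_study(cfg)
    pipe_cfg = write_study_inputs(study, RESULTS / "data")
    pipe_cfg.out_dir = str(RESULTS)
    pipe_cfg.seed = SEED
    pipe_cfg.ngs_roh_bin_bp = cfg.tile_bp  # sequence-ROH bins scaled to the toy genome
    pipe_cfg.to_json(RESULTS / "pipeline_config.json")

    truth = study.truth
    pd.Series(truth.true_f, name="true_f").rename_axis("individual").reset_index().to_csv(
        RESULTS / "ground_truth_f.tsv", sep="\t", index=False
    )
    rows = [
        (ind, chrom, s, e)
        for ind, ivs in truth.implanted_roh.items()
        for chrom, s, e in ivs
    ]
    pd.DataFrame(rows, columns=["individual", "chrom", "start", "end"]).to_csv(
        RESULTS / "ground_truth_roh.tsv", sep="\t", index=False
    )
    truth.fixed_differences.to_csv(
        RESULTS / "ground_truth_fixed_differences.tsv", sep="\t", index=False
    )

    n_fd = len(truth.fixed_differences)
    print(f"cohort: {study.chip.n_samples} pigs, {study.chip.n_markers} chip markers, "
          f"{cfg.n_snps_seq} sequence SNPs on {cfg.n_chromosomes} x {cfg.chrom_length_bp / 1e6:.0f} Mb")
    print(f"implanted ROH per sequenced pig: {cfg.n_roh_long} long (1.5-4 Mb), "
          f"{cfg.n_roh_short} short (120-190 kb)")
    print(f"true fixed differences (implants + accidental): {n_fd} records")
    print(f"inputs written under {RESULTS / 'data'}")


if __name__ == "__main__":
    main()
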