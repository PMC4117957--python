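"""Pairwise FST between breeds and the breed dendrogram.

Weir-Cockerham ratio-of-sums FST over the QC-passed chip markers for
every breed pair, then UPGMA and neighbour-joining trees from the
matrix.  With the drift parameters used by the generator the two local
breeds are more distant from each other than either is from the larger
commercial pool, which the tree topology reflects.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

from pigpop import fst, io as pio


def main() -> None:
    data = RESULTS / "data"
    g = pio.read_genotype_matrix(data / "chip.tsv", populations=data / "populations.tsv")
    g, _ = pio.filter_chip_markers(g)

    m = fst.fst_matrix(g)
    m.to_csv(RESULTS / "fst_matrix.tsv", sep="\t")
    upgma = fst.fst_dendrogram(m, "upgma")
    nj = fst.fst_dendrogram(m, "nj")
    (RESULTS / "fst_tree_upgma.nwk").write_text(upgma + "\n")
    (RESULTS / "fst_tree_nj.nwk").write_text(nj + "\n")

    print("pairwise FST (WC84, ratio of sums):")
    print(m.round(4).to_string())
    print(f"\nUPGMA: {upgma}")
    print(f"NJ:    {nj}")


if __name__ == "__main__":
    main()
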