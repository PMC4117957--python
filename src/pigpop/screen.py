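"""The fixed-difference screen over non-synonymous SNPs.

A non-synonymous SNP is retained for a local breed when the pooled
commercial group and that breed are fixed for different alleles
(per-locus FST = 1), under explicit genotype rules that take precedence
over the estimator:

* every typed commercial pig is homozygous for the same allele, and at
  most three of the commercial pigs may be missing at the locus;
* both sequenced animals of the local breed are homozygous for the
  other allele — breeds with a single sequenced animal, or with missing
  data in one of their two animals, contribute nothing at that locus.

Retained records are polarized against an outgroup genome: when the
outgroup is homozygous for one of the two segregating alleles, that
allele is called ancestral and the record notes whether the derived
allele is the one fixed in the local breed or in the commercial pool;
a heterozygous or missing outgroup leaves the record unpolarized.
"""

from __future__ import annotations

import warnings
from collections import defaultdict

import numpy as np
import pandas as pd

from .containers import (
    MISSING,
    FixedDifferenceRecord,
    ParameterError,
    VariantTable,
)


def _genotype_map(vt: VariantTable, functional_only: bool = True) -> dict[tuple[str, int], int]:
    rec = vt.nonsynonymous() if functional_only else vt.snps
    return dict(zip(zip(rec["chrom"], rec["pos"]), rec["genotype"].astype(int)))


def screen_fixed_differences(
    variant_tables: dict[str, VariantTable],
    groups: dict[str, list[str]],
    commercial: list[str],
    max_commercial_missing: int = 3,
    genes: pd.DataFrame | None = None,
) -> list[FixedDifferenceRecord]:
    """Find non-synonymous SNPs fixed for different alleles between the
    pooled commercial pigs and each local breed.

    ``groups`` maps local breed -> sequenced individuals; breeds with
    fewer than two individuals are skipped with a warning.  ``genes``
    (chrom, start, end, name; half-open intervals) attaches gene names
    by overlap.
    """
    if not commercial:
        raise ParameterError("commercial group is empty")
    comm_maps = {s: _genotype_map(variant_tables[s]) for s in commercial}

    # union of non-synonymous loci with their alleles / damage labels
    locus_info: dict[tuple[str, int], tuple[str, str, str]] = {}
    for vt in variant_tables.values():
        for r in vt.nonsynonymous().itertuples(index=False):
            locus_info.setdefault((r.chrom, r.pos), (r.ref, r.alt, r.damage_label))

    gene_lookup = _gene_lookup(genes) if genes is not None else None
    records: list[FixedDifferenceRecord] = []
    for breed, members in sorted(groups.items()):
        present = [s for s in members if s in variant_tables]
        if len(present) < 2:
            warnings.warn(
                f"breed {breed}: {len(present)} sequenced animal(s); excluded from the screen",
                stacklevel=2,
            )
            continue
        local_maps = [_genotype_map(variant_tables[s]) for s in present]
        for locus in sorted(locus_info):
            ref, alt, damage = locus_info[locus]
            cg = [comm_maps[s].get(locus, MISSING) for s in commercial]
            typed = [x for x in cg if x != MISSING]
            if len(cg) - len(typed) > max_commercial_missing or not typed:
                continue
            if any(x == 1 for x in typed) or len(set(typed)) != 1:
                continue
            comm_code = typed[0]
            lg = [m.get(locus, MISSING) for m in local_maps]
            if any(x == MISSING for x in lg):
                continue  # missing data in a local animal disqualifies the breed here
            if any(x == 1 for x in lg) or len(set(lg)) != 1 or lg[0] == comm_code:
                continue
            chrom, pos = locus
            records.append(
                FixedDifferenceRecord(
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    local_breed=breed,
                    commercial_allele=ref if comm_code == 0 else alt,
                    local_allele=ref if lg[0] == 0 else alt,
                    n_local_hom=len(lg),
                    n_commercial_typed=len(typed),
                    gene=gene_lookup(chrom, pos) if gene_lookup else "none",
                    damage_label=damage,
                )
            )
    return records


def _gene_lookup(genes: pd.DataFrame):
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for chrom, sub in genes.groupby("chrom", sort=False):
        trees[chrom] = IntervalTree.from_tuples(
            (int(r.start), int(r.end), str(r.name))
            for r in sub.itertuples(index=False)
            if r.end > r.start
        )

    def lookup(chrom: str, pos: int) -> str:
        tree = trees.get(chrom)
        if tree is None:
            return "none"
        hits = tree[pos]
        return min(h.data for h in hits) if hits else "none"

    return lookup


def polarize(
    records: list[FixedDifferenceRecord], outgroup: VariantTable
) -> list[FixedDifferenceRecord]:
    """Fill ancestral/derived status from the outgroup genotype.

    The ancestral allele is the outgroup's homozygous allele when it is
    one of the two segregating alleles; a heterozygous, missing or
    absent outgroup call leaves the record unknown.
    """
    og = _genotype_map(outgroup, functional_only=False)
    out = []
    for r in records:
        code = og.get((r.chrom, r.pos), MISSING)
        if code == 0:
            anc = r.ref
        elif code == 2:
            anc = r.alt
        else:
            out.append(r)
            continue
        if anc == r.commercial_allele:
            derived_in = "local"
        elif anc == r.local_allele:
            derived_in = "commercial"
        else:  # outgroup fixed for a third allele
            out.append(r)
            continue
        out.append(
            FixedDifferenceRecord(
                **{
                    **r.__dict__,
                    "ancestral_allele": anc,
                    "derived_fixed_in": derived_in,
                }
            )
        )
    return out


def summarize_screen(records: list[FixedDifferenceRecord]) -> dict:
    """Counts over the screen output: SNPs, genes, per-breed and
    damage-label breakdowns, and the derived-allele polarity split."""
    loci = {(r.chrom, r.pos) for r in records}
    genes = {r.gene for r in records if r.gene != "none"}
    per_breed: dict[str, int] = defaultdict(int)
    damage: dict[str, int] = defaultdict(int)
    polarity: dict[str, int] = defaultdict(int)
    for r in records:
        per_breed[r.local_breed] += 1
        damage[r.damage_label] += 1
        polarity[r.derived_fixed_in] += 1
    known = polarity["local"] + polarity["commercial"]
    return {
        "n_records": len(records),
        "n_snps": len(loci),
        "n_genes": len(genes),
        "per_breed": dict(per_breed),
        "damage": dict(damage),
        "polarity": dict(polarity),
        "pct_derived_fixed_local": 100.0 * polarity["local"] / known if known else float("nan"),
        "pct_derived_fixed_commercial": 100.0 * polarity["commercial"] / known if known else float("nan"),
    }


def records_to_frame(records: list[FixedDifferenceRecord]) -> pd.DataFrame:
    """One row per record, 1-based positions for the on-disk table."""
    cols = [
        "chrom",
        "pos",
        "ref",
        "alt",
        "local_breed",
        "commercial_allele",
        "local_allele",
        "n_local_hom",
        "n_commercial_typed",
        "gene",
        "damage_label",
        "ancestral_allele",
        "derived_fixed_in",
    ]
    df = pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records], columns=cols)
    if len(df):
        df["pos"] = df["pos"] + 1
    return df
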