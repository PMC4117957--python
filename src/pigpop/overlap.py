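"""Permutation test of SNP-QTL overlap.

Are the screened non-synonymous SNPs inside a QTL category's intervals
more often than random draws from the genome-wide non-synonymous pool?
Each resample draws the same number of SNPs uniformly without
replacement from the pool and records how many fall inside at least one
interval of the category (a SNP covered by two intervals counts once).
The empirical p-value uses the add-one rule

    p = (1 + #{resamples with count >= observed}) / (1 + n_perm)

so p can never be exactly zero.  Because draws are exchangeable the
null count is hypergeometric in the number of pool SNPs covered by the
category; ``exact=True`` reports that tail probability instead of
resampling (no add-one, it is the exhaustive enumeration).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import OverlapTestResult, ParameterError, QTLSet


Snp = tuple[str, int]


def _coverage_flags(snps: Sequence[Snp], qtls: QTLSet, category: str) -> np.ndarray:
    """Boolean per SNP: inside >=1 interval of the category."""
    sub = qtls.category(category)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, rows in sub.groupby("chrom", sort=False):
        ivs = sorted(zip(rows["start"], rows["end"]))
        merged: list[tuple[int, int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        starts = np.array([s for s, _ in merged])
        ends = np.array([e for _, e in merged])
        by_chrom[chrom] = (starts, ends)
    flags = np.zeros(len(snps), dtype=bool)
    for i, (chrom, pos) in enumerate(snps):
        if chrom not in by_chrom:
            continue
        starts, ends = by_chrom[chrom]
        j = int(np.searchsorted(starts, pos, side="right")) - 1
        flags[i] = j >= 0 and pos < ends[j]
    return flags


def overlap_count(snps: Sequence[Snp], qtls: QTLSet, category: str) -> int:
    """Number of SNPs inside at least one interval of the category."""
    return int(_coverage_flags(snps, qtls, category).sum())


def permutation_test(
    screened: Sequence[Snp],
    pool: Sequence[Snp],
    qtls: QTLSet,
    category: str,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    exact: bool = False,
) -> OverlapTestResult:
    """Upper-tail permutation test of the screened set's QTL overlap.

    ``screened`` must be a subset of ``pool``.  With ``exact=True`` the
    hypergeometric tail over all C(|pool|, k) equally likely draws is
    reported instead of a Monte Carlo estimate.
    """
    pool = list(pool)
    screened = list(screened)
    k = len(screened)
    if k > len(pool):
        raise ParameterError(f"screened set ({k}) larger than pool ({len(pool)})")
    pool_set = set(pool)
    outside = [s for s in screened if s not in pool_set]
    if outside:
        raise ParameterError(f"screened SNPs not in pool: {outside[:3]}...")
    flags = _coverage_flags(pool, qtls, category)
    observed = overlap_count(screened, qtls, category)
    N, K = len(pool), int(flags.sum())
    if exact:
        p = float(stats.hypergeom.sf(observed - 1, N, K, k))
        return OverlapTestResult(category, observed, np.array([], dtype=int), p, 0, None, True)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    null_counts = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        draw = rng.choice(N, size=k, replace=False)
        null_counts[i] = int(flags[draw].sum())
    p = (1.0 + (null_counts >= observed).sum()) / (1.0 + n_perm)
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    return OverlapTestResult(category, observed, null_counts, float(p), n_perm, seed_val, False)


def test_all_categories(
    screened: Sequence[Snp],
    pool: Sequence[Snp],
    qtls: QTLSet,
    n_perm: int = 1000,
    seed: int | None = None,
    bh_column: bool = False,
) -> tuple[pd.DataFrame, list[OverlapTestResult]]:
    """Run the permutation test per QTL category.

    Per-category seeds are spawned from ``seed`` so categories are
    independent but the whole table is reproducible.  Raw p-values are
    reported; ``bh_column`` adds a Benjamini-Hochberg adjusted column.
    """
    ss = np.random.SeedSequence(seed)
    results = []
    for cat, child in zip(qtls.categories(), ss.spawn(len(qtls.categories()))):
        results.append(
            permutation_test(
                screened, pool, qtls, cat, n_perm, np.random.default_rng(child)
            )
        )
    df = pd.DataFrame(
        {
            "category": [r.category for r in results],
            "observed": [r.observed_overlap for r in results],
            "k": len(list(screened)),
            "null_mean": [float(r.null_counts.mean()) if len(r.null_counts) else np.nan for r in results],
            "p": [r.p_value for r in results],
            "n_perm": [r.n_perm for r in results],
        }
    )
    if bh_column:
        df["p_bh"] = _benjamini_hochberg(df["p"].to_numpy())
    return df, results


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    from scipy.stats import false_discovery_control

    return false_discovery_control(p, method="bh")
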