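"""Independently coded brute-force oracles.

Each oracle recomputes a statistic from first principles (loops,
enumeration, ANOVA sums) without touching the implementation's code
paths, so agreement is evidence of correctness rather than tautology.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

MISSING = -1


# ---------------------------------------------------------------------------
# diversity estimators
# ---------------------------------------------------------------------------

def ho_oracle(calls: np.ndarray) -> float:
    """Observed heterozygosity: plain double loop over loci/samples."""
    ratios = []
    n_samples, n_loci = calls.shape
    for j in range(n_loci):
        het = typed = 0
        for i in range(n_samples):
            if calls[i, j] != MISSING:
                typed += 1
                if calls[i, j] == 1:
                    het += 1
        if typed:
            ratios.append(het / typed)
    return float(np.mean(ratios)) if ratios else float("nan")


def he_oracle(calls: np.ndarray) -> float:
    """Unbiased gene diversity averaged over loci."""
    vals = []
    n_samples, n_loci = calls.shape
    for j in range(n_loci):
        alleles = []
        for i in range(n_samples):
            g = calls[i, j]
            if g != MISSING:
                alleles.extend([1] * int(g) + [0] * (2 - int(g)))
        n = len(alleles) // 2
        if n == 0:
            continue
        p = sum(alleles) / len(alleles)
        vals.append((2.0 * n / (2.0 * n - 1.0)) * (1.0 - p * p - (1.0 - p) ** 2))
    return float(np.mean(vals)) if vals else float("nan")


def f_oracle(calls: np.ndarray, row: int) -> float:
    """Method-of-moments inbreeding coefficient for sample ``row``."""
    n_samples, n_loci = calls.shape
    o_hom = 0
    e_hom = 0.0
    L = 0
    for j in range(n_loci):
        if calls[row, j] == MISSING:
            continue
        alt = tot = 0
        for i in range(n_samples):
            if calls[i, j] != MISSING:
                alt += int(calls[i, j])
                tot += 2
        p = alt / tot
        N = tot // 2
        e_hom += 1.0 - 2.0 * p * (1.0 - p) * (2.0 * N / (2.0 * N - 1.0))
        L += 1
        if calls[row, j] in (0, 2):
            o_hom += 1
    denom = L - e_hom
    if abs(denom) < 1e-12:
        return float("nan")
    return (o_hom - e_hom) / denom


# ---------------------------------------------------------------------------
# Weir-Cockerham theta via the ANOVA mean-squares route
# ---------------------------------------------------------------------------

def theta_anova_oracle(counts: np.ndarray) -> float:
    """WC84 theta from allele-frequency ANOVA on raw genotype counts.

    counts: (n_pops, 3) genotype counts [hom-ref, het, hom-alt].
    Populations without data are dropped.  Returns NaN when the design
    degenerates (fewer than 2 informative populations, no within-
    population degrees of freedom, or a monomorphic locus).
    """
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts.sum(axis=1) > 0]
    r = len(counts)
    if r < 2:
        return float("nan")
    n = counts.sum(axis=1)
    n_tot = n.sum()
    if n_tot - r <= 0 or n_tot <= r:  # no within-pop df
        return float("nan")
    p = (counts[:, 1] + 2.0 * counts[:, 2]) / (2.0 * n)
    h = counts[:, 1] / n
    p_bar = float((n * p).sum() / n_tot)

    # within-individual (gametes) sum of squares: 0.5 per heterozygote
    ssg = 0.5 * float(counts[:, 1].sum())
    msg = ssg / n_tot
    # between individuals within populations
    ssi = 0.0
    for i in range(r):
        for code, x in ((0, 0.0), (1, 0.5), (2, 1.0)):
            ssi += counts[i, code] * 2.0 * (x - p[i]) ** 2
    msi = ssi / (n_tot - r)
    # between populations
    ssp = float((2.0 * n * (p - p_bar) ** 2).sum())
    msp = ssp / (r - 1.0)
    n_c = (n_tot - float((n**2).sum()) / n_tot) / (r - 1.0)

    s2_g = msg
    s2_i = (msi - msg) / 2.0
    s2_p = (msp - msi) / (2.0 * n_c)
    denom = s2_p + s2_i + s2_g
    if denom == 0.0 or not math.isfinite(denom):
        return float("nan")
    return s2_p / denom


# ---------------------------------------------------------------------------
# chip ROH by exhaustive segment enumeration
# ---------------------------------------------------------------------------

def chip_roh_oracle(
    pos: np.ndarray,
    geno: np.ndarray,
    min_snps: int = 20,
    max_het: int = 1,
    min_len: int = 10_000,
    min_density: float = 0.0,
    max_gap: int = 1_000_000,
) -> set[tuple[int, int]]:
    """All maximal marker segments satisfying the chip-ROH constraints,
    as half-open bp intervals anchored on homozygous end markers."""
    n = len(pos)
    passing = []
    for a in range(n):
        if geno[a] not in (0, 2):
            continue
        for b in range(a, n):
            if geno[b] not in (0, 2):
                continue
            seg = geno[a : b + 1]
            if int((seg == 1).sum()) > max_het:
                continue
            hom = int(((seg == 0) | (seg == 2)).sum())
            if hom < min_snps:
                continue
            length = int(pos[b]) + 1 - int(pos[a])
            if length < min_len:
                continue
            if b > a and int(np.diff(pos[a : b + 1]).max()) > max_gap:
                continue
            if hom / length < min_density:
                continue
            passing.append((a, b))
    maximal = [
        (a, b)
        for (a, b) in passing
        if not any(a2 <= a and b <= b2 and (a2, b2) != (a, b) for (a2, b2) in passing)
    ]
    return {(int(pos[a]), int(pos[b]) + 1) for a, b in maximal}


# ---------------------------------------------------------------------------
# overlap test by exhaustive enumeration
# ---------------------------------------------------------------------------

def exact_overlap_p_oracle(in_category: list[bool], k: int, observed: int) -> float:
    """Upper-tail probability of >= observed overlaps over all C(n, k)
    equally likely draws (feasible for small pools)."""
    draws = list(combinations(in_category, k))
    hits = sum(1 for d in draws if sum(d) >= observed)
    return hits / len(draws)
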