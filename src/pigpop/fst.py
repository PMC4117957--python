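"""Population differentiation: Weir-Cockerham theta and FST dendrograms.

Per-locus theta is the 1984 variance-components estimator
``a / (a + b + c)`` computed from per-population sample sizes, allele
frequencies and observed heterozygote fractions; multi-locus values use
the ratio-of-sums ``sum(a) / sum(a + b + c)``.  Negative per-locus
estimates are kept (clamping would bias the ratio); theta = 1 exactly
when the populations are fixed for different alleles with no missing
data.  Missing genotypes simply shrink the population's sample size at
that locus.

Breed trees are built from the pairwise FST matrix with UPGMA (default;
leaves are sorted lexicographically so ties break deterministically) or
neighbour joining, serialized as Newick with branch lengths.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, MISSING, ParameterError


@dataclass
class FstResult:
    """Per-locus Weir-Cockerham components for one biallelic locus."""

    locus: str
    theta: float
    a: float
    b: float
    c: float
    freqs: np.ndarray  # per-population alt-allele frequency
    sizes: np.ndarray  # per-population diploid sample size


def genotype_counts(g: GenotypeMatrix, pops: list[str] | None = None) -> np.ndarray:
    """Per-population genotype counts, shape (n_pops, n_loci, 3)."""
    pops = pops or g.population_labels()
    labels = np.array([g.populations[s] for s in g.sample_ids])
    out = np.zeros((len(pops), g.n_markers, 3), dtype=np.int64)
    for i, pop in enumerate(pops):
        calls = g.calls[labels == pop]
        for code in (0, 1, 2):
            out[i, :, code] = (calls == code).sum(axis=0)
    return out


def _wc_components(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised WC84 (a, b, c) for counts of shape (r, L, 3).

    Loci where fewer than two populations have data, or where the
    finite-sample terms degenerate (n_bar <= 1), yield NaN components.
    """
    counts = np.asarray(counts, dtype=float)
    r_pops, L, _ = counts.shape
    n = counts.sum(axis=2)  # (r, L) diploid sizes
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (counts[:, :, 1] + 2.0 * counts[:, :, 2]) / (2.0 * n)
        h = counts[:, :, 1] / n
    informative = n > 0
    r = informative.sum(axis=0).astype(float)  # populations with data per locus
    n_sum = n.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        n_bar = n_sum / r
        n_c = (n_sum - (n**2).sum(axis=0) / n_sum) / (r - 1.0)
        p_bar = np.nansum(n * p, axis=0) / n_sum
        s2 = np.nansum(n * (p - p_bar) ** 2, axis=0) / ((r - 1.0) * n_bar)
        h_bar = np.nansum(n * h, axis=0) / n_sum
        inner = p_bar * (1.0 - p_bar) - (r - 1.0) / r * s2
        a = (n_bar / n_c) * (s2 - (inner - h_bar / 4.0) / (n_bar - 1.0))
        b = (n_bar / (n_bar - 1.0)) * (inner - (2.0 * n_bar - 1.0) / (4.0 * n_bar) * h_bar)
        c = h_bar / 2.0
    bad = (r < 2) | (n_bar <= 1.0) | ~np.isfinite(n_c) | (n_c <= 0)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def per_locus_fst(counts: np.ndarray, locus: str = "") -> FstResult:
    """Weir-Cockerham theta at one biallelic locus.

    ``counts`` has shape (n_pops, 3): hom-ref, het, hom-alt per
    population.  Monomorphic loci give theta = NaN.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 3:
        raise ParameterError("counts must have shape (n_pops, 3)")
    if (counts.sum(axis=1) > 0).sum() < 2:
        raise ParameterError("need >=2 populations with at least one typed diploid")
    a, b, c = _wc_components(counts[:, None, :])
    a, b, c = float(a[0]), float(b[0]), float(c[0])
    denom = a + b + c
    theta = a / denom if np.isfinite(denom) and denom != 0.0 else float("nan")
    n = counts.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (counts[:, 1] + 2 * counts[:, 2]) / (2 * n)
    return FstResult(locus, theta, a, b, c, p, n)


def pairwise_fst(
    g: GenotypeMatrix,
    pop_a: str | list[str],
    pop_b: str | list[str],
    loci: np.ndarray | None = None,
) -> float:
    """Multi-locus ratio-of-sums FST between two (pooled) populations.

    ``pop_a``/``pop_b`` may be lists of population labels to pool (the
    commercial lines are pooled this way).  ``loci`` is an optional
    boolean mask or index array restricting the loci used.
    """
    labels = np.array([g.populations[s] for s in g.sample_ids])
    set_a = {pop_a} if isinstance(pop_a, str) else set(pop_a)
    set_b = {pop_b} if isinstance(pop_b, str) else set(pop_b)
    calls_a = g.calls[np.isin(labels, list(set_a))]
    calls_b = g.calls[np.isin(labels, list(set_b))]
    if loci is not None:
        calls_a, calls_b = calls_a[:, loci], calls_b[:, loci]
    counts = np.stack(
        [
            np.stack([(c == code).sum(axis=0) for code in (0, 1, 2)], axis=1)
            for c in (calls_a, calls_b)
        ]
    )
    a, b, c = _wc_components(counts)
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    denom = (a + b + c)[ok].sum()
    if not ok.any() or denom == 0.0:
        return float("nan")
    return float(a[ok].sum() / denom)


def fst_matrix(
    g: GenotypeMatrix,
    populations: list[str] | None = None,
    loci: np.ndarray | None = None,
) -> pd.DataFrame:
    """Square symmetric pairwise-FST matrix over populations."""
    pops = populations or g.population_labels()
    m = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, pa in enumerate(pops):
        for pb in pops[i + 1 :]:
            v = pairwise_fst(g, pa, pb, loci)
            m.loc[pa, pb] = m.loc[pb, pa] = v
    return m


# ---------------------------------------------------------------------------
# dendrograms
# ---------------------------------------------------------------------------

def fst_dendrogram(m: pd.DataFrame, method: str = "upgma") -> str:
    """Hierarchical tree (Newick, with branch lengths) from an FST matrix.

    Small negative estimates are clamped to zero for tree building.
    """
    if m.isna().to_numpy().any():
        raise ParameterError("FST matrix is incomplete")
    labels = sorted(m.index)  # lexicographic order fixes tie-breaking
    d = m.loc[labels, labels].to_numpy(dtype=float)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    np.fill_diagonal(d, 0.0)
    if method == "upgma":
        return _upgma_newick(d, labels)
    if method == "nj":
        return _nj_newick(d, labels)
    raise ParameterError(f"unknown tree method {method!r}")


def _upgma_newick(d: np.ndarray, labels: list[str]) -> str:
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    Z = linkage(squareform(d, checks=False), method="average")
    n = len(labels)
    newick: dict[int, str] = {}
    height: dict[int, float] = {i: 0.0 for i in range(n)}
    for i in range(n):
        newick[i] = labels[i]
    for k, (li, ri, dist, _) in enumerate(Z):
        li, ri = int(li), int(ri)
        h = dist / 2.0
        bl_l = h - height[li]
        bl_r = h - height[ri]
        node = n + k
        newick[node] = f"({newick[li]}:{bl_l:.6g},{newick[ri]}:{bl_r:.6g})"
        height[node] = h
    return newick[2 * n - 2] + ";"


def _nj_newick(d: np.ndarray, labels: list[str]) -> str:
    from skbio import DistanceMatrix
    from skbio.tree import nj

    tree = nj(DistanceMatrix(d, ids=labels))
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()
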