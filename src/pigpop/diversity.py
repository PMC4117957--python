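"""Diversity statistics from chip genotypes and sequence variants.

Chip side: observed heterozygosity Ho, unbiased expected heterozygosity
He (gene diversity with the 2n/(2n-1) small-sample correction), and the
per-individual inbreeding coefficient F measured as the excess of
observed over expected homozygosity,

    F = (O_hom - E_hom) / (L - E_hom),

with E_hom summed over the individual's typed loci from total-sample
allele frequencies (the method-of-moments estimator used by chip QC
software; negative values flag recent outcrossing).

Sequence side: heterozygous sites per 50-kb bin divided by the callable
sites in the bin (depth within [7x, 2 x mean]); bins with too few
callable sites are dropped, and an individual's h_NGS is the mean over
retained bins.  Population h_NGS averages its individuals.

Concordance between the two marker systems is summarised with Pearson
correlations at population level (Ho, He vs h_NGS) and individual level
(F vs h_NGS).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    MISSING,
    CallabilityTrack,
    GenotypeMatrix,
    ParameterError,
    VariantTable,
)


@dataclass
class DiversitySummary:
    """Per-population and per-individual diversity estimates."""

    per_population: pd.DataFrame  # population, Ho, He, F, h_ngs
    per_individual: pd.DataFrame  # individual, population, F, h_ngs


# ---------------------------------------------------------------------------
# chip estimators
# ---------------------------------------------------------------------------

def _pop_masks(g: GenotypeMatrix) -> dict[str, np.ndarray]:
    pops = g.population_labels()
    labels = np.array([g.populations[s] for s in g.sample_ids])
    return {p: labels == p for p in pops}


def observed_heterozygosity(g: GenotypeMatrix, by_population: bool = True) -> dict[str, float]:
    """Mean over loci of the heterozygote fraction among non-missing calls."""
    out = {}
    masks = _pop_masks(g) if by_population else {"all": np.ones(g.n_samples, bool)}
    for pop, mask in masks.items():
        calls = g.calls[mask]
        typed = (calls != MISSING).sum(axis=0)
        het = (calls == 1).sum(axis=0)
        ok = typed > 0
        out[pop] = float(np.mean(het[ok] / typed[ok])) if ok.any() else float("nan")
    return out


def expected_heterozygosity(g: GenotypeMatrix, by_population: bool = True) -> dict[str, float]:
    """Unbiased gene diversity (2n/(2n-1)) * (1 - p^2 - q^2), averaged
    over all loci with at least one typed diploid (monomorphic included)."""
    out = {}
    masks = _pop_masks(g) if by_population else {"all": np.ones(g.n_samples, bool)}
    for pop, mask in masks.items():
        calls = g.calls[mask]
        typed = (calls != MISSING).sum(axis=0)
        alt = np.where(calls == MISSING, 0, calls).sum(axis=0)
        ok = typed > 0
        n = typed[ok].astype(float)
        p = alt[ok] / (2.0 * n)
        he = (2.0 * n / (2.0 * n - 1.0)) * (1.0 - p**2 - (1.0 - p) ** 2)
        out[pop] = float(he.mean()) if ok.any() else float("nan")
    return out


def inbreeding_coefficient(g: GenotypeMatrix, individual: str) -> float:
    """Method-of-moments F for one individual against total-sample
    allele frequencies.  Loci where the individual is untyped are
    excluded; returns NaN when the denominator degenerates."""
    row = g.calls[g.sample_index(individual)]
    use = row != MISSING
    if not use.any():
        return float("nan")
    calls = g.calls[:, use]
    typed = (calls != MISSING).sum(axis=0).astype(float)
    alt = np.where(calls == MISSING, 0, calls).sum(axis=0)
    p = alt / (2.0 * typed)
    q = 1.0 - p
    # E[hom] per locus, with the finite-sample correction on 2pq
    e_hom = 1.0 - 2.0 * p * q * (2.0 * typed / (2.0 * typed - 1.0))
    L = int(use.sum())
    o_hom = int(np.isin(row[use], (0, 2)).sum())
    e_total = float(e_hom.sum())
    denom = L - e_total
    if abs(denom) < 1e-12:
        return float("nan")
    return (o_hom - e_total) / denom


def inbreeding_coefficients(g: GenotypeMatrix) -> pd.Series:
    """F for every sample, indexed by sample id."""
    return pd.Series(
        {s: inbreeding_coefficient(g, s) for s in g.sample_ids}, name="F"
    )


# ---------------------------------------------------------------------------
# sequence-based heterozygosity
# ---------------------------------------------------------------------------

def binned_heterozygosity(
    v: VariantTable,
    track: CallabilityTrack,
    bin_bp: int = 50_000,
    depth_floor: int = 7,
    depth_ceiling: float | None = None,
    min_callable_fraction: float = 0.2,
) -> tuple[pd.DataFrame, float]:
    """Heterozygous SNPs per bin over callable sites per bin.

    Returns the per-bin table (retained bins only) and the individual's
    h_NGS (mean of per-bin h).  ``depth_ceiling`` defaults to twice the
    track's genome-wide mean depth; heterozygous calls outside the
    depth window do not count in the numerator, mirroring the callable
    denominator.
    """
    if bin_bp % track.tile_bp:
        raise ParameterError(f"bin_bp must be a multiple of the {track.tile_bp}-bp tiles")
    if depth_ceiling is None:
        depth_ceiling = 2.0 * track.mean_depth
    snps = v.snps
    hets = snps[
        (snps["genotype"] == 1)
        & (snps["depth"] >= depth_floor)
        & (snps["depth"] <= depth_ceiling)
    ]
    rows = []
    for chrom, length in track.chrom_lengths.items():
        n_bins = length // bin_bp  # trailing partial bin is ignored
        if n_bins == 0:
            continue
        edges = np.arange(n_bins + 1) * bin_bp
        pos = hets.loc[hets["chrom"] == chrom, "pos"].to_numpy()
        het_counts = np.histogram(pos, bins=edges)[0]
        tiles_per_bin = bin_bp // track.tile_bp
        tile_counts = track.counts[chrom][: n_bins * tiles_per_bin]
        callable_per_bin = tile_counts.reshape(n_bins, tiles_per_bin).sum(axis=1)
        for b in range(n_bins):
            rows.append((chrom, int(edges[b]), int(callable_per_bin[b]), int(het_counts[b])))
    bins = pd.DataFrame(rows, columns=["chrom", "bin_start", "callable", "n_het"])
    retained = bins[bins["callable"] >= min_callable_fraction * bin_bp].copy()
    if retained.empty:
        return retained.assign(h=np.nan), float("nan")
    retained["h"] = retained["n_het"] / retained["callable"]
    return retained, float(retained["h"].mean())


def population_h_ngs(h_by_individual: pd.Series, populations: dict[str, str]) -> pd.Series:
    """Mean h_NGS over each population's sequenced individuals."""
    df = pd.DataFrame(
        {"h": h_by_individual, "pop": [populations[s] for s in h_by_individual.index]}
    )
    return df.groupby("pop")["h"].mean()


# ---------------------------------------------------------------------------
# summary + concordance
# ---------------------------------------------------------------------------

def diversity_summary(
    g: GenotypeMatrix,
    variant_tables: dict[str, VariantTable],
    tracks: dict[str, CallabilityTrack],
    bin_bp: int = 50_000,
    depth_floor: int = 7,
    min_callable_fraction: float = 0.2,
) -> DiversitySummary:
    """Assemble the per-breed diversity table (Ho, He, F, h_NGS)."""
    ho = observed_heterozygosity(g)
    he = expected_heterozygosity(g)
    f = inbreeding_coefficients(g)
    h_ind = pd.Series(
        {
            sid: binned_heterozygosity(
                vt, tracks[sid], bin_bp, depth_floor, None, min_callable_fraction
            )[1]
            for sid, vt in variant_tables.items()
        }
    )
    per_ind = pd.DataFrame(
        {
            "individual": g.sample_ids,
            "population": [g.populations[s] for s in g.sample_ids],
            "F": [f[s] for s in g.sample_ids],
            "h_ngs": [h_ind.get(s, np.nan) for s in g.sample_ids],
        }
    )
    rows = []
    for pop in g.population_labels():
        members = g.population_samples(pop)
        seq = [s for s in members if s in h_ind.index]
        rows.append(
            (
                pop,
                ho[pop],
                he[pop],
                float(np.mean([f[s] for s in members])),
                float(np.mean([h_ind[s] for s in seq])) if seq else np.nan,
            )
        )
    per_pop = pd.DataFrame(rows, columns=["population", "Ho", "He", "F", "h_ngs"])
    return DiversitySummary(per_pop, per_ind)


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan"), int(len(x))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r, p = stats.pearsonr(x, y)
    return float(r), float(p), int(len(x))


def concordance(summary: DiversitySummary) -> pd.DataFrame:
    """Pearson correlations between chip and sequence diversity:
    (Ho, h_NGS) and (He, h_NGS) at population level, (F, h_NGS) at
    individual level.  Undefined correlations are reported as NaN."""
    pp, pi = summary.per_population, summary.per_individual
    rows = []
    for a, b, level, df in [
        ("Ho", "h_ngs", "population", pp),
        ("He", "h_ngs", "population", pp),
        ("F", "h_ngs", "individual", pi),
    ]:
        r, p, n = _pearson(df[a].to_numpy(float), df[b].to_numpy(float))
        rows.append((f"{a}~h_NGS", level, r, p, n))
    return pd.DataFrame(rows, columns=["pair", "level", "r", "p", "n"])
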