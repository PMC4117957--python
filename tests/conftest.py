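from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pigpop.containers import GenotypeMatrix
from pigpop.synthetic import SimConfig, SimulatedStudy, simulate_study


def matrix_from(
    geno: np.ndarray,
    pos: np.ndarray | None = None,
    chrom: str = "1",
    populations: dict[str, str] | None = None,
) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a (samples x loci) genotype array."""
    geno = np.asarray(geno, dtype=np.int8)
    if geno.ndim == 1:
        geno = geno[None, :]
    n_samples, n_loci = geno.shape
    if pos is None:
        pos = np.arange(n_loci) * 10_000
    sample_ids = [f"s{i + 1}" for i in range(n_samples)]
    markers = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.asarray(pos, dtype=int),
            "id": [f"m{j}" for j in range(n_loci)],
            "ref": "A",
            "alt": "C",
        }
    )
    pops = populations or {s: "P" for s in sample_ids}
    return GenotypeMatrix(sample_ids, pops, markers, geno)


@pytest.fixture(scope="session")
def study() -> SimulatedStudy:
    """The default synthetic study, shared across tests (seed fixed)."""
    return simulate_study(SimConfig(seed=1))
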