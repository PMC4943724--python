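import numpy as np
import pandas as pd
import pytest

from pleioscan import GenotypeMatrix
from pleioscan.synthetic import SyntheticConfig, generate_genotypes


def make_marker_map(chroms, bps, prefix="s"):
    m = len(chroms)
    return pd.DataFrame(
        {
            "chrom": [str(c) for c in chroms],
            "marker_id": [f"{prefix}{i}" for i in range(m)],
            "bp": list(bps),
            "a1": "A",
            "a2": "B",
        }
    )


def make_gm(dosages, chroms=None, bps=None):
    """GenotypeMatrix from a raw dosage array with an auto-generated map."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    chroms = ["1"] * m if chroms is None else chroms
    bps = range(1000, 1000 * (m + 1), 1000) if bps is None else bps
    return GenotypeMatrix(
        dosages,
        np.array([f"ind{i}" for i in range(n)]),
        make_marker_map(chroms, bps),
    )


@pytest.fixture(scope="session")
def small_genotypes():
    """300 individuals x 2,000 markers on 5 chromosomes, fixed seed."""
    cfg = SyntheticConfig(
        n_individuals=300, n_markers=2000, n_chromosomes=5, n_genes=40, seed=11
    )
    return cfg, generate_genotypes(cfg)
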