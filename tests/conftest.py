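import numpy as np
import pandas as pd
import pytest

from merinogp.containers import GenotypeMatrix


def make_markers(m, chrom="1", prefix="snp"):
    return pd.DataFrame(
        {
            "id": [f"{prefix}{j + 1}" for j in range(m)],
            "chrom": chrom,
            "pos": np.arange(1, m + 1) * 100,
            "a1": "A",
            "a2": "G",
        }
    )


@pytest.fixture
def tiny_gm():
    """3 individuals x 4 markers, one missing cell."""
    d = np.array(
        [
            [0.0, 1.0, 2.0, 1.0],
            [1.0, 1.0, 0.0, np.nan],
            [2.0, 1.0, 1.0, 0.0],
        ]
    )
    return GenotypeMatrix(d, ["i1", "i2", "i3"], make_markers(4))


@pytest.fixture
def small_dataset():
    """Complete simulated dataset reused across model tests."""
    from merinogp.sim import SimConfig, simulate_dataset

    cfg = SimConfig(
        n_individuals=150, n_markers_high=200, n_markers_low=40,
        missing_rate=0.0, h2_target=0.5, seed=42,
    )
    return simulate_dataset(cfg)
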