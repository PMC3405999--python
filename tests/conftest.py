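import numpy as np
import pandas as pd
import pytest

from prcmap import SimulationConfig, simulate_chip_arrays


@pytest.fixture(scope="session")
def small_config():
    """Single-mark simulation small enough for per-test reuse."""
    return SimulationConfig(
        n_genes=400,
        n_chromosomes=5,
        marks=("H2AK119u1",),
        positive_fraction=0.1,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_chip_arrays(small_config)


@pytest.fixture(scope="session")
def noisefree_flat_config():
    """Flat peaks, zero noise: every value is exactly 0 or the amplitude."""
    return SimulationConfig(
        n_genes=120,
        n_chromosomes=3,
        marks=("H2AK119u1",),
        positive_fraction=0.25,
        peak_shape="flat",
        peak_amplitude=2.0,
        noise_sd=0.0,
        expression_noise_sd=0.0,
        close_pair_fraction=0.0,
        seed=3,
    )


@pytest.fixture(scope="session")
def noisefree_flat_sim(noisefree_flat_config):
    return simulate_chip_arrays(noisefree_flat_config)


@pytest.fixture
def tiny_probe_frame():
    """Hand-built probe table: one gene, two probes, ratios 1 and 4."""

    def build(log2_ratios=(0.0, 2.0), mark="H2AK119u1", condition="control"):
        rows = []
        for i, r in enumerate(log2_ratios):
            mid = 1000 + i * 250
            rows.append(
                {
                    "probe_id": f"chr1:{mid}",
                    "chrom": "chr1",
                    "start": mid - 125,
                    "end": mid + 125,
                    "mark": mark,
                    "condition": condition,
                    "replicate": 1,
                    "log2_ratio": r,
                }
            )
        return pd.DataFrame(rows)

    return build


@pytest.fixture
def tiny_genes():
    return pd.DataFrame(
        {"gene_id": ["geneA"], "chrom": ["chr1"], "tss": [1000], "strand": ["+"]}
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
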