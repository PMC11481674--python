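"""Shared fixtures: small simulated fields reused across test modules."""

import numpy as np
import pytest

from cortiquant import SimulationConfig, simulate_field


@pytest.fixture(scope="session")
def default_field():
    """Membrane-bound scenario, realistic noise, 10 cells."""
    cfg = SimulationConfig(seed=42, n_cells=10)
    return cfg, *simulate_field(cfg)


@pytest.fixture(scope="session")
def noisefree_field():
    """Noise-free, blur-on field for oracle comparisons."""
    cfg = SimulationConfig(seed=43, n_cells=6, noise=False)
    return cfg, *simulate_field(cfg)


@pytest.fixture(scope="session")
def twochannel_field():
    """Colocalized two-channel field with 0.1 um arc jitter."""
    cfg = SimulationConfig(seed=44, n_cells=8, channel2_mode="colocalized",
                           colocalization_jitter=0.1, membrane_fraction=0.7,
                           puncta_enrichment=0.8)
    return cfg, *simulate_field(cfg)


@pytest.fixture
def disc_mask():
    """Exact rasterized disc of radius 25 px, label 1, in a 64x64 field."""
    from cortiquant import LabelMask
    rr, cc = np.mgrid[0:64, 0:64]
    return LabelMask(((rr - 32) ** 2 + (cc - 32) ** 2 <= 25**2).astype(int))
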