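import numpy as np
import pytest

from nucassembly import simulate as sim


@pytest.fixture(scope="session")
def noiseless_field():
    """Three disjoint nuclei, no noise, no markers: geometry is exact."""
    cfg = sim.ImageSimConfig(
        field_size_px=(384, 384), n_nuclei=3, camera_noise_sd=0, seed=1,
        shape_irregularity=0.0,
    )
    return sim.generate_cell_field(cfg), cfg


@pytest.fixture(scope="session")
def noisy_field():
    """Default-noise field with an enriched marker, for recovery tests."""
    cfg = sim.ImageSimConfig(
        field_size_px=(700, 700), n_nuclei=12, seed=5,
        marker_specs=[
            sim.MarkerSpec("H2A.Z", nuclear_mean=120.0, cytoplasm_mean=12.0),
            sim.MarkerSpec("H3K9me3", nuclear_mean=80.0, cytoplasm_mean=10.0,
                           periphery_enrichment=2.0),
            sim.MarkerSpec("mAB414", nuclear_mean=30.0, cytoplasm_mean=15.0,
                           ne_ring_enrichment=4.0),
        ],
    )
    return sim.generate_cell_field(cfg), cfg


def disk_mask(shape, center, radius):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2
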