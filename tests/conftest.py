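import logging

import numpy as np
import pytest

import orientem as om
from orientem.simulate import make_phantom, required_L, simulate_dataset

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def grid24():
    return om.build_grid(24, seed=1)


@pytest.fixture(scope="session")
def geom16():
    return om.shannon_geometry(16, 1.0)


@pytest.fixture(scope="session")
def phantom16(geom16):
    vol, blobs = make_phantom(n_blobs=6, box_diameter=1.0, seed=2,
                              L=required_L(geom16, 0.5), voxel_spacing=0.5)
    return vol, blobs


@pytest.fixture(scope="session")
def node_dataset(grid24, geom16, phantom16):
    """High-signal snapshots at the 24 grid nodes, 10 each (1e4 photons)."""
    vol, _ = phantom16
    quats = np.repeat(grid24.nodes, 10, axis=0)
    data = simulate_dataset(vol, geom16, N=len(quats), mean_photons=1e4,
                            seed=3, orientations=quats)
    truth_idx = np.repeat(np.arange(len(grid24)), 10)
    return data, truth_idx


@pytest.fixture(scope="session")
def noisy_dataset(geom16, phantom16):
    vol, _ = phantom16
    return simulate_dataset(vol, geom16, N=200, mean_photons=300, seed=11)
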