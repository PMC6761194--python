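import numpy as np
import pytest

import synquery as sq


@pytest.fixture(scope="session")
def sparse_scene():
    """Default-noise simulated volume with roughly fifty synapses."""
    cfg = sq.SimulationConfig(seed=11)
    scale = 50 / (sum(cfg.densities.values())
                  * cfg.geometry.total_volume_um3 * (1 - cfg.nuclei_fraction))
    cfg = cfg.with_density_scale(scale)
    channels, truth, nuclei = sq.generate_volume(cfg)
    return cfg, channels, truth, nuclei


@pytest.fixture(scope="session")
def sparse_probs(sparse_scene):
    _, channels, _, _ = sparse_scene
    return sq.channel_probabilities(
        {n: c for n, c in channels.items() if n != "DAPI"})


@pytest.fixture(scope="session")
def queries():
    return sq.standard_queries()


def make_geometry(nz=6, h=20, w=20):
    return sq.AcquisitionGeometry(n_slices=nz, height_px=h, width_px=w)


@pytest.fixture
def small_geometry():
    return make_geometry()


def random_prob_channels(seed, geometry, names=("A", "B", "C", "D")):
    """Independent uniform-probability channels, for algebraic property tests."""
    rng = np.random.default_rng(seed)
    return {name: sq.ProbabilityVolume(name, rng.uniform(size=geometry.shape),
                                       geometry)
            for name in names}
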