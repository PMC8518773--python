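import numpy as np
import pytest

import biocrust as bc


@pytest.fixture(scope="session")
def default_scene() -> bc.Scene:
    """One default synthetic site shared by read-only tests."""
    return bc.generate_scene(bc.SceneConfig(seed=7))


@pytest.fixture(scope="session")
def noise_free_scene() -> bc.Scene:
    """A fully deterministic site: no reflectance, thermal or moisture noise."""
    cfg = bc.SceneConfig(seed=8, reflectance_noise_sd=0.0, thermal_noise_sd=0.0,
                         moisture_link=(12.0, 8.0, -6.0, 0.0))
    return bc.generate_scene(cfg)


def make_plane(nrows=9, ncols=9, cell=1.0, gx=0.0, gy=0.0, z0=100.0):
    """Planar DTM helper: z = z0 + gx*x + gy*y."""
    g = bc.Grid(nrows=nrows, ncols=ncols, cell_size=cell)
    x, y = g.cell_centers()
    return bc.Raster(g, z0 + gx * x + gy * y)
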