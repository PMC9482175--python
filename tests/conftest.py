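"""Shared fixtures: small synthetic scenes at a coarse raster.

Scenes are generated at 1-2 um/pixel rather than the production
0.25 um/pixel so the suite stays fast; the geometry and cell model are
unchanged.
"""

import numpy as np
import pytest

from periscore.config import SimulationConfig, UnmixConfig
from periscore.synthetic import render_brightfield, simulate_core
from periscore.unmixing import StainBasis


@pytest.fixture(scope="session")
def basis():
    return StainBasis()


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=11, n_patients=6, cores_per_patient=1, core_diameter=600.0,
        pixel_size=2.0, regions=("CT",), tumour_fraction=0.3,
        proximity_enrichment={"CD8": 3.0})


@pytest.fixture(scope="session")
def ct_scene(small_config):
    return simulate_core(small_config, "P001", "CT")


@pytest.fixture(scope="session")
def fine_scene():
    cfg = SimulationConfig(seed=5, core_diameter=600.0, pixel_size=1.0,
                           regions=("CT",), tumour_fraction=0.3)
    return simulate_core(cfg, "P001", "CT")


@pytest.fixture(scope="session")
def fine_render(fine_scene, basis):
    return render_brightfield(fine_scene, basis, noise_sd=0.0)


@pytest.fixture(scope="session")
def exact_unmix_config():
    """Solver settings for exactness checks: no sparsity, no background
    floor, tight tolerance."""
    return UnmixConfig(lam=0.0, od_floor=0.0, tol=1e-10, max_iter=5000)
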