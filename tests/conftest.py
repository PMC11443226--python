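"""Shared fixtures: tiny planting scenes and scaled-down season configs.

Full-season runs use desk-scale plots (a few dozen plants) so the whole
suite stays fast; the physics and carbon bookkeeping are identical to
production-size scenes.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from daylily_fspm.canopy_light import OpticalProps, SceneGeometry, TracerConfig
from daylily_fspm.scenarios import load_table1
from daylily_fspm.simulator import SimulationConfig, run
from daylily_fspm.weather_sky import SolarGeometry, SyntheticWeatherConfig, build_sky_dome


CATALOGUE = {s.id: s for s in load_table1()}


def tiny_config(scenario_id: int = 5, **overrides) -> SimulationConfig:
    """Small-plot season config used by the simulator-level tests."""
    defaults = dict(
        scenario=CATALOGUE[scenario_id],
        seed=1,
        n_facets=1,
        plot_target=(2.0, 0.8),
        tracer=TracerConfig(min_source_fraction=0.01),
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_id5_result():
    """One shared small-plot full-season run of the default scenario."""
    return run(tiny_config(5))


@pytest.fixture(scope="session")
def noon_dome():
    """Midsummer dome at the model's default site, 300 W m-2, cloud 0.4."""
    return build_sky_dome(300.0, SolarGeometry(40.13, 113.9, 172), 0.4)


def horizontal_leaf_scene(heights: list[float], side: float = 1.0) -> SceneGeometry:
    """Stack of horizontal square leaves centred on the origin."""
    n = len(heights)
    origins = np.array([[-side / 2, -side / 2, z] for z in heights])
    u = np.tile([side, 0.0, 0.0], (n, 1))
    v = np.tile([0.0, side, 0.0], (n, 1))
    return SceneGeometry(
        origins=origins, u_vecs=u, v_vecs=v,
        leaf_index=np.arange(n), n_leaves=n,
    )


def random_leaf_scene(n: int = 20, seed: int = 1) -> SceneGeometry:
    """Random parallelogram leaves in a ~1.5 m box (cross-mode test scene)."""
    rng = np.random.default_rng(seed)
    o = rng.uniform(0.0, 1.5, (n, 3))
    o[:, 2] = rng.uniform(0.0, 1.0, n)
    u = rng.normal(0.0, 0.3, (n, 3))
    v = np.cross(u, rng.normal(0.0, 1.0, (n, 3)))
    v = v / np.linalg.norm(v, axis=1, keepdims=True) * 0.12
    return SceneGeometry(
        origins=o, u_vecs=u, v_vecs=v, leaf_index=np.arange(n), n_leaves=n
    )
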