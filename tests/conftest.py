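"""Shared fixtures: geometries, meshes and (expensive) steady flow solves.

Flow solves are session-scoped so that physics tests and acceptance tests
share one solution per operating point.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from centrisim import config as ccfg
from centrisim import flow as cflow
from centrisim import forces as cforces
from centrisim import geometry as cgeo
from centrisim import mixing as cmix

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")

UM = 1e-6


@pytest.fixture(scope="session")
def fluid():
    return cflow.Fluid()


@pytest.fixture(scope="session")
def lift_model():
    return cforces.LiftModel.default()


@pytest.fixture(scope="session")
def separator_geometry():
    return cgeo.build_contraction_expansion_channel()


@pytest.fixture(scope="session")
def separator_mesh(separator_geometry):
    return cgeo.generate_mesh(separator_geometry, 5 * UM)


@pytest.fixture(scope="session")
def short_separator_geometry():
    """Two-unit separator for cheap flow/tracking physics tests."""
    return cgeo.build_contraction_expansion_channel(
        cgeo.ContractionExpansionSpec(n_units=2)
    )


@pytest.fixture(scope="session")
def short_separator_mesh(short_separator_geometry):
    return cgeo.generate_mesh(short_separator_geometry, 5 * UM)


@pytest.fixture(scope="session")
def short_separator_flow(short_separator_mesh, fluid):
    return cflow.solve_flow(
        short_separator_mesh, fluid, cflow.RotatingFrame.from_rpm(2000),
        tol_rate=0.05, max_steps=8000,
    )


@pytest.fixture(scope="session")
def mixer_geometry():
    return cgeo.build_serpentine_mixer()


@pytest.fixture(scope="session")
def mixer_mesh(mixer_geometry):
    return cgeo.generate_mesh(mixer_geometry, 5 * UM)


@pytest.fixture(scope="session")
def mixer_flow(mixer_mesh, fluid):
    return cflow.solve_flow(
        mixer_mesh, fluid, cflow.RotatingFrame.from_rpm(2000),
        tol_rate=0.05, max_steps=8000,
    )


@pytest.fixture(scope="session")
def mixer_concentration(mixer_flow):
    return cmix.solve_concentration(mixer_flow, peclet=cmix.DEFAULT_PECLET)


@pytest.fixture(scope="session")
def duct_section():
    return cgeo.ChannelSection(100 * UM, 50 * UM, 500 * UM)


@pytest.fixture(scope="session")
def duct_geometry(duct_section):
    return cgeo.build_straight_channel(duct_section)


@pytest.fixture(scope="session")
def duct_mesh(duct_geometry):
    return cgeo.generate_mesh(duct_geometry, 5 * UM)


@pytest.fixture(scope="session")
def default_populations():
    return [
        (cforces.Particle(10 * UM, label="WBC"), 20),
        (cforces.Particle(20 * UM, label="CTC"), 20),
    ]


@pytest.fixture(scope="session")
def presets_table():
    return ccfg.presets()


def assert_close(actual, expected, sig=6):
    """Agreement to ``sig`` significant figures."""
    assert actual == pytest.approx(expected, rel=10.0 ** (1 - sig) / 2)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
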