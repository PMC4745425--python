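"""Shared fixtures: reference model objects and cached simulation runs.

The heavier 1D simulations are session-scoped so the physics tests and the
acceptance checks share one run each of the default three-segment model,
the uniform stiff (near-rigid) tube, and the steady-inflow case.
"""

import numpy as np
import pytest

from artwave.model import (
    SegmentedVessel,
    VesselGeometry,
    WallMaterial,
    build_default_model,
    default_fluid,
)
from artwave.pulsewave import SolverSettings, simulate
from artwave.waveform import MeanVelocitySeries, default_waveform_params, generate_waveform

STIFF = WallMaterial(youngs_modulus=200e6, poissons_ratio=0.499)
COMPLIANT = WallMaterial(youngs_modulus=5e6, poissons_ratio=0.499)


@pytest.fixture(scope="session")
def fluid():
    return default_fluid()


@pytest.fixture(scope="session")
def geometry():
    return VesselGeometry(inner_diameter=0.008, outer_diameter=0.010)


@pytest.fixture(scope="session")
def default_model():
    return build_default_model()


@pytest.fixture(scope="session")
def uniform_stiff_vessel(geometry):
    """Uniform 200 MPa tube with the default probe positions."""
    return SegmentedVessel(
        segments=((0.150, STIFF),),
        inlet_extension_length=0.030,
        extension_material=STIFF,
        geometry=geometry,
    )


@pytest.fixture(scope="session")
def default_run(default_model, fluid):
    """Default three-segment simulation: 3 cycles, dx = 0.5 mm."""
    return simulate(default_model, fluid=fluid)


@pytest.fixture(scope="session")
def coarse_run(default_model, fluid):
    """Same model at dx = 1 mm, for the grid-convergence comparison."""
    return simulate(default_model, fluid=fluid, settings=SolverSettings(dx=1e-3))


@pytest.fixture(scope="session")
def rigid_run(uniform_stiff_vessel, fluid):
    """Pulsatile run of the near-rigid uniform tube, frequency-corrected WSS."""
    return simulate(
        uniform_stiff_vessel,
        fluid=fluid,
        settings=SolverSettings(wss_model="womersley"),
    )


@pytest.fixture(scope="session")
def steady_run(uniform_stiff_vessel, fluid):
    """Constant-inflow run of the uniform tube (Poiseuille oracle case)."""
    t = np.linspace(0.0, 1.0, 65)
    waveform = MeanVelocitySeries(times=t, values=np.full(65, 0.2))
    return simulate(
        uniform_stiff_vessel,
        waveform=waveform,
        fluid=fluid,
        settings=SolverSettings(cycles=2),
    )


@pytest.fixture(scope="session")
def default_waveform():
    return generate_waveform(default_waveform_params(), n_samples=256)
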