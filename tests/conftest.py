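"""Shared fixtures.  The expensive reference runs (equilibrium spindle,
one-pole release, calibration points, FRAP curves) are session-scoped so the
end-to-end tests and the property tests reuse a single computation."""

import numpy as np
import pytest

from mtseq.calibration import effective_binding_rate
from mtseq.geometry import EnergidDomain, MicrotubuleSet, SpindleSpec, build_spindle
from mtseq.mean_field import FieldParams, run_frap
from mtseq.scenarios import fig1_one_pole_release, fig1_symmetric


@pytest.fixture(scope="session")
def small_spindle():
    spec = SpindleSpec(n_spindle=100, n_astral=100)
    return build_spindle(spec, seed=0)


@pytest.fixture(scope="session")
def single_mt():
    """One microtubule along z through the origin, poles at the minus end."""
    return MicrotubuleSet(
        minus=[[0.0, 0.0, -5.0]], plus=[[0.0, 0.0, 5.0]], pole_id=[0],
        pole_positions=[[0.0, 0.0, -5.0]])


@pytest.fixture(scope="session")
def fig1_equilibrium():
    return fig1_symmetric(scale=0.2, duration=20.0, seeds=(1, 2, 3))


@pytest.fixture(scope="session")
def one_pole_release():
    return fig1_one_pole_release(scale=0.2, duration=10.0, seeds=(1, 2, 3))


@pytest.fixture(scope="session")
def calibration_point_5nm():
    return effective_binding_rate(3.0, particle_radius=0.005, k_off=1.0,
                                  seed=0, duration=120.0, n_particles=32)


@pytest.fixture(scope="session")
def coarse_domain():
    return EnergidDomain(spacing=1.0)


@pytest.fixture(scope="session")
def frap_sequestered(coarse_domain):
    return run_frap(coarse_domain, FieldParams(k_on=5.0), duration=300.0, dt=0.25)


@pytest.fixture(scope="session")
def frap_pure(coarse_domain):
    neighbor = coarse_domain.subdomain_center_cell(3, 2)
    return run_frap(coarse_domain, FieldParams(k_on=0.0), duration=60.0, dt=0.05,
                    extra_monitor_cells={"neighbor": neighbor})
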