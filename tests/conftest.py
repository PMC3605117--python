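"""Shared fixtures: the term-pregnancy parameter set and the heavier
simulation artifacts reused across test modules (session-scoped)."""

from __future__ import annotations

import numpy as np
import pytest

import uterosim as us
from uterosim.conductivity import ConductivityModel, TensorField
from uterosim.fhn import PacemakerSpec
from uterosim.meshing import ball_mesh, spherical_shell_mesh
from uterosim.params import SolverConfig
from uterosim.volume_conductor import VolumeConductorSystem


@pytest.fixture(scope="session")
def params() -> us.IonicParams:
    return us.IonicParams()


@pytest.fixture(scope="session")
def cond() -> ConductivityModel:
    return us.design_conductivities()


@pytest.fixture(scope="session")
def cable_series(params, cond):
    """End-stimulated 20 cm cable with the term parameter set (reused by
    waveform, speed and acceptance tests)."""
    return us.simulate_cable_front(
        params, cond.sigma_el, cond.varsigma, length=0.2, h=5.0e-4, dt=0.01
    )


@pytest.fixture(scope="session")
def ball_conductor():
    """Homogeneous conducting ball with its factorized volume-conductor
    system (dipole-oracle validations)."""
    R, sigma = 0.1, 0.33
    mesh = ball_mesh(R, subdiv=3, n_layers=8)
    cm = ConductivityModel(
        sigma_el=1.0,
        sigma_et=0.5,
        varsigma=0.8,
        compartments=us.CompartmentConductivities(G_A=sigma),
    )
    tf = TensorField(lambda r: np.array([0.0, 0.0, 1.0]), 1.0, 0.5)
    system = VolumeConductorSystem(mesh, cm, tf, lam=0.0)
    return {"mesh": mesh, "system": system, "R": R, "sigma": sigma}


@pytest.fixture(scope="session")
def shell_run(params, cond):
    """Single-pacemaker contraction on a (size-reduced) spherical shell.

    The shell radius is scaled to 4 cm so the traveling front (width ~3 mm)
    is resolved at desk scale; the wave physics (parameters, fiber angle,
    pacemaker protocol) is the term-pregnancy configuration.
    """
    R_out, wall = 0.04, 0.005
    mesh = spherical_shell_mesh(R_out - wall, R_out, subdiv=4, n_layers=2)
    alpha = np.deg2rad(45.0)
    tf = TensorField(
        lambda r: us.spherical_fiber_direction(r, alpha),
        cond.sigma_el,
        cond.sigma_et,
    )
    ops = us.assemble_operators(mesh, tf, cond.varsigma, params)
    pm = PacemakerSpec.fundus_cap(
        nu=2.0, t_off=0.1, r_min=R_out - wall, r_max=R_out,
        z_min=0.85 * (R_out - wall),
    )
    cfg = SolverConfig(dt=0.02, t_end=50.0, output_stride=25)
    v, w = us.run_monodomain(mesh, ops, params, [pm], cfg)
    return {"mesh": mesh, "v": v, "tensor": tf, "alpha": alpha}


@pytest.fixture(scope="session")
def refractory_value(params) -> float:
    return us.refractory_period(params)
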