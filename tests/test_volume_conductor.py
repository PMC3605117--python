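"""Elliptic interface solves: gauge, linearity, analytic dipole oracle,
vernix switch."""

import numpy as np
import pytest
from scipy.special import eval_legendre

import uterosim as us
from uterosim.conductivity import ConductivityModel, TensorField
from uterosim.fibers import spherical_fiber_direction
from uterosim.geometry import Boundary, Compartment, build_spherical_geometry
from uterosim.meshing import ball_mesh, four_compartment_mesh
from uterosim.monodomain import FieldSeries
from uterosim.params import CompartmentConductivities, GeometryConfig
from uterosim.volume_conductor import (
    VolumeConductorSystem,
    solve_potential_series,
    solve_potentials,
)


def _monopole_surface_series(robs, r_src, I, R, sigma, nmax=80):
    """Surface potential of a point current source inside an insulated
    homogeneous sphere (classical Legendre series)."""
    b = np.linalg.norm(r_src)
    rhat = robs / np.linalg.norm(robs, axis=1, keepdims=True)
    cosg = rhat @ (r_src / b) if b > 0 else np.ones(len(robs))
    out = np.zeros(len(robs))
    for n in range(1, nmax):
        out += (2 * n + 1) / n * (b**n / R ** (n + 1)) * eval_legendre(n, cosg)
    return I / (4 * np.pi * sigma) * out


def dipole_surface_oracle(robs, r0, p_vec, R, sigma, split=1e-6):
    """Two-monopole limit of the dipole surface potential."""
    phat = p_vec / np.linalg.norm(p_vec)
    I = np.linalg.norm(p_vec) / split
    return _monopole_surface_series(
        robs, r0 + 0.5 * split * phat, I, R, sigma
    ) - _monopole_surface_series(robs, r0 - 0.5 * split * phat, I, R, sigma)


def _subtraction_solve(ball, r0, q):
    """Solve the homogeneous-sphere dipole problem with the singular part
    handled analytically (secondary-potential formulation)."""
    mesh, system, sigma = ball["mesh"], ball["system"], ball["sigma"]

    def grad_phi_inf(pts):
        d = pts - r0
        dist = np.linalg.norm(d, axis=1, keepdims=True)
        return (q[None, :] - 3 * d * (d @ q)[:, None] / dist**2) / (
            4 * np.pi * sigma * dist**3
        )

    fc = mesh.facet_centroids()
    n_hat = fc / np.linalg.norm(fc, axis=1, keepdims=True)
    g = -sigma * np.einsum("fi,fi->f", grad_phi_inf(fc), n_hat)
    areas = mesh.facet_areas()
    rhs = np.zeros(mesh.num_nodes)
    np.add.at(rhs, mesh.facets.ravel(), np.repeat(g * areas / 3.0, 3))
    sol = system.solve(rhs)
    d = mesh.points - r0
    dist = np.linalg.norm(d, axis=1)
    phi_inf = (d @ q) / (4 * np.pi * sigma * np.maximum(dist, 1e-12) ** 3)
    return sol.phi + phi_inf


class TestBasicProperties:
    def test_constant_vm_gives_zero_potential(self, ball_conductor):
        mesh = ball_conductor["mesh"]
        # use a four-compartment setup so M elements exist
        geo = build_spherical_geometry(GeometryConfig())
        mesh4 = four_compartment_mesh(geo, subdiv=1, layers=(2, 1, 2, 2))
        cm = us.design_conductivities()
        tf = TensorField(
            lambda r: spherical_fiber_direction(r, np.pi / 4),
            cm.sigma_el,
            cm.sigma_et,
        )
        v = np.full(mesh4.num_nodes, -0.056)
        sol = solve_potentials(mesh4, v, cm, tf, lam=0.0)
        finite = np.isfinite(sol.phi)
        assert np.max(np.abs(sol.phi[finite])) < 1e-12

    def test_linearity_in_source(self, ball_conductor):
        system = ball_conductor["system"]
        mesh = ball_conductor["mesh"]
        rng = np.random.default_rng(1)
        rhs = rng.normal(size=mesh.num_nodes)
        rhs -= rhs.mean()
        p1 = system.solve(rhs).phi
        p2 = system.solve(2 * rhs).phi
        assert np.allclose(p2, 2 * p1, rtol=1e-10, atol=1e-16)

    def test_discrete_operator_symmetric(self, ball_conductor):
        mesh = ball_conductor["mesh"]
        from uterosim import fem

        K = fem.stiffness_matrix(mesh, ball_conductor["sigma"])
        assert abs(K - K.T).max() < 1e-12

    def test_gauge_zero_mean_on_surface(self, ball_conductor):
        system = ball_conductor["system"]
        mesh = ball_conductor["mesh"]
        rng = np.random.default_rng(2)
        rhs = rng.normal(size=mesh.num_nodes)
        rhs -= rhs.mean()
        phi = system.solve(rhs).phi
        gauge_nodes = system.gauge_nodes
        assert abs(phi[gauge_nodes].mean()) < 1e-12


class TestDipoleOracle:
    @pytest.mark.parametrize("orient", ["radial", "tangential"])
    def test_surface_potential_matches_series(self, ball_conductor, orient):
        R, sigma = ball_conductor["R"], ball_conductor["sigma"]
        mesh = ball_conductor["mesh"]
        r0 = np.array([0.0, 0.0, 0.5 * R])
        q = np.array([0, 0, 1e-8]) if orient == "radial" else np.array([1e-8, 0, 0])
        phi = _subtraction_solve(ball_conductor, r0, q)
        outer = np.unique(mesh.facets)
        got = phi[outer] - phi[outer].mean()
        want = dipole_surface_oracle(mesh.points[outer], r0, q, R, sigma)
        want -= want.mean()
        err = np.linalg.norm(got - want) / np.linalg.norm(want)
        assert err < 0.02

    def test_error_decreases_under_refinement(self):
        R, sigma = 0.1, 0.33
        r0 = np.array([0.0, 0.0, 0.5 * R])
        q = np.array([1e-8, 0.0, 0.0])
        errs = []
        for subdiv, layers in [(1, 2), (2, 4), (3, 8)]:
            mesh = ball_mesh(R, subdiv, layers)
            cm = ConductivityModel(
                sigma_el=1.0,
                sigma_et=0.5,
                varsigma=0.8,
                compartments=CompartmentConductivities(G_A=sigma),
            )
            tf = TensorField(lambda r: np.array([0.0, 0.0, 1.0]), 1.0, 0.5)
            system = VolumeConductorSystem(mesh, cm, tf, lam=0.0)
            ball = {"mesh": mesh, "system": system, "sigma": sigma, "R": R}
            phi = _subtraction_solve(ball, r0, q)
            outer = np.unique(mesh.facets)
            got = phi[outer] - phi[outer].mean()
            want = dipole_surface_oracle(mesh.points[outer], r0, q, R, sigma)
            want -= want.mean()
            errs.append(np.linalg.norm(got - want) / np.linalg.norm(want))
        assert errs[0] > errs[1] > errs[2]


@pytest.fixture(scope="module")
def four_comp_setup():
    geo = build_spherical_geometry(GeometryConfig())
    mesh = four_compartment_mesh(geo, subdiv=2, layers=(2, 2, 2, 2))
    cm = us.design_conductivities()
    tf = TensorField(
        lambda r: spherical_fiber_direction(r, np.pi / 4), cm.sigma_el, cm.sigma_et
    )
    # synthetic depolarization pattern on the wall: upper half excited
    z = mesh.points[:, 2]
    v = np.where(z > 0.0, -0.016, -0.056)
    return {"geo": geo, "mesh": mesh, "cm": cm, "tf": tf, "v": v}


class TestFourCompartment:
    def test_no_net_current_leaves_the_conductor(self, four_comp_setup):
        """Discrete no-flux: the variational nodal currents K phi - rhs
        vanish to solver tolerance, so no net current crosses the abdominal
        surface (divergence theorem on the discrete system)."""
        s = four_comp_setup
        mesh, cm = s["mesh"], s["cm"]
        system = VolumeConductorSystem(mesh, cm, s["tf"], lam=0.0)
        rhs = system.source_from_vm(np.asarray(s["v"], dtype=float))
        sol = system.solve(rhs)
        from uterosim import fem

        act = system.active_nodes
        labels = mesh.cell_labels
        centroids = mesh.cell_centroids()
        d = mesh.dim
        G = np.zeros((mesh.num_cells, d, d))
        eye = np.eye(d)
        G[labels == Compartment.M] = (
            (cm.varsigma + 1.0) / cm.varsigma
        ) * np.asarray(s["tf"](centroids[labels == Compartment.M]))
        G[labels == Compartment.A] = cm.compartments.G_A * eye
        G[labels == Compartment.U] = cm.compartments.G_U * eye
        K = fem.stiffness_matrix(
            mesh, G[system.active_cells], cells_mask=system.active_cells
        )
        resid = (K @ np.nan_to_num(sol.phi) - rhs)[act]
        # residual is the gauge multiplier spread uniformly; its mean-free
        # part (the physical nodal currents) vanishes to solver tolerance
        resid -= resid.mean()
        assert np.max(np.abs(resid)) < 1e-10 * max(np.abs(rhs).max(), 1e-30)

    def test_vernix_switch_changes_surface_potential(self, four_comp_setup):
        s = four_comp_setup
        mesh = s["mesh"]
        phi0 = solve_potentials(mesh, s["v"], s["cm"], s["tf"], lam=0.0).phi
        phi1 = solve_potentials(mesh, s["v"], s["cm"], s["tf"], lam=1.0).phi
        da_nodes = np.unique(mesh.facets[mesh.facet_labels == Boundary.dA])
        d0, d1 = phi0[da_nodes], phi1[da_nodes]
        rel = np.linalg.norm(d0 - d1) / np.linalg.norm(d0)
        assert rel > 0.01  # a conductive fetus measurably changes the EMG
        # with vernix (lam=0) the fetal interior is excluded from the solve
        f_interior = [
            n
            for n in mesh.compartment_nodes(Compartment.F)
            if n not in set(np.unique(mesh.facets[mesh.facet_labels == Boundary.dF]))
        ]
        assert np.all(np.isnan(phi0[f_interior]))
        assert np.all(np.isfinite(phi1[f_interior]))

    def test_series_identical_snapshots(self, four_comp_setup):
        s = four_comp_setup
        mesh = s["mesh"]
        vs = FieldSeries(
            mesh, [0.0, 1.0], np.vstack([s["v"], s["v"]]), "v_m", "V"
        )
        phis = solve_potential_series(mesh, vs, s["cm"], s["tf"], lam=0.0)
        assert np.array_equal(phis.values[0], phis.values[1], equal_nan=True)
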