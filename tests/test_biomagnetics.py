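"""Currents and Biot-Savart magnetics: textbook loop field, spherical
conductor silence/Sarvas oracles, divergence-free flux, anisotropy rotation."""

import numpy as np
import pytest

import uterosim as us
from uterosim import fem
from uterosim.biomagnetics import (
    MU0,
    SensorArray,
    biot_savart,
    impressed_current,
    magnetic_field,
    mmg_projection,
)
from uterosim.conductivity import TensorField
from uterosim.meshing import spherical_shell_mesh


def _sarvas(q, r0, robs):
    """Closed-form magnetic field of a current dipole in a spherically
    symmetric conductor (independent oracle)."""
    out = np.empty((len(robs), 3))
    for i, r in enumerate(robs):
        a = r - r0
        na, nr = np.linalg.norm(a), np.linalg.norm(r)
        F = na * (nr * na + nr**2 - r0 @ r)
        gF = (na**2 / nr + a @ r / na + 2 * na + 2 * nr) * r - (
            na + 2 * nr + a @ r / na
        ) * r0
        out[i] = (
            MU0
            / (4 * np.pi * F**2)
            * (F * np.cross(q, r0) - (np.cross(q, r0) @ r) * gF)
        )
    return out


@pytest.fixture(scope="module")
def blob_fields(ball_conductor):
    """Radial and tangential compact current sources in the conducting
    ball, solved for return currents."""
    mesh = ball_conductor["mesh"]
    system = ball_conductor["system"]
    sigma = ball_conductor["sigma"]
    R = ball_conductor["R"]
    cent = mesh.cell_centroids()
    vols = mesh.cell_volumes()
    r0 = np.array([0.0, 0.0, 0.5 * R])
    a = 0.015
    w = np.exp(-0.5 * (np.linalg.norm(cent - r0, axis=1) / a) ** 2)
    w /= (w * vols).sum()
    p = 1e-8
    out = {}
    th = np.linspace(0, 2 * np.pi, 13)[:-1]
    obs = np.column_stack(
        [1.5 * R * np.cos(th), 1.5 * R * np.sin(th), np.full_like(th, 0.02)]
    )
    for name, q in (("radial", np.array([0, 0, p])), ("tangential", np.array([p, 0, 0]))):
        Js = np.outer(w, q)
        rhs = -fem.divergence_rhs(mesh, Js)
        phi = system.solve(rhs).phi
        J = Js - sigma * fem.gradient_of_nodal_field(mesh, phi)
        out[name] = {"J": J, "q": q, "B": magnetic_field(mesh, J, obs)}
    out["obs"] = obs
    out["r0"] = r0
    out["mesh"] = mesh
    return out


class TestLoopField:
    def test_circular_loop_center_field(self):
        R, I, nseg = 0.05, 1.0, 1000
        th = np.linspace(0, 2 * np.pi, nseg + 1)
        pts = np.column_stack([R * np.cos(th), R * np.sin(th), np.zeros(nseg + 1)])
        mid = 0.5 * (pts[1:] + pts[:-1])
        dl = I * (pts[1:] - pts[:-1])
        B = biot_savart(mid, dl, np.zeros((1, 3)))
        assert B[0, 2] == pytest.approx(MU0 * I / (2 * R), rel=0.01)
        assert abs(B[0, 0]) < 1e-12 and abs(B[0, 1]) < 1e-12


class TestSphericalConductorOracles:
    def test_radial_dipole_is_magnetically_silent(self, blob_fields):
        b_rad = np.abs(blob_fields["radial"]["B"]).max()
        b_tan = np.abs(blob_fields["tangential"]["B"]).max()
        assert b_rad < 0.01 * b_tan

    def test_tangential_dipole_matches_sarvas(self, blob_fields):
        B = blob_fields["tangential"]["B"]
        Bs = _sarvas(
            blob_fields["tangential"]["q"], blob_fields["r0"], blob_fields["obs"]
        )
        err = np.linalg.norm(B - Bs) / np.linalg.norm(Bs)
        assert err < 0.05

    def test_divergence_free_net_flux(self, blob_fields):
        """Net flux of B through a closed sensor sphere vanishes."""
        mesh = blob_fields["mesh"]
        J = blob_fields["tangential"]["J"]
        rng = np.random.default_rng(0)
        # Fibonacci sphere of radius 0.18 around the conductor
        n = 200
        i = np.arange(n) + 0.5
        z = 1 - 2 * i / n
        r = np.sqrt(1 - z**2)
        phi = np.pi * (3 - np.sqrt(5)) * i
        dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
        obs = 0.18 * dirs
        B = magnetic_field(mesh, J, obs)
        area = 4 * np.pi * 0.18**2 / n
        flux = (np.einsum("si,si->s", B, dirs) * area).sum()
        scale = (np.linalg.norm(B, axis=1) * area).sum()
        assert abs(flux) < 0.01 * scale

    def test_superposition_in_current(self, blob_fields):
        mesh = blob_fields["mesh"]
        obs = blob_fields["obs"]
        J1 = blob_fields["radial"]["J"]
        J2 = blob_fields["tangential"]["J"]
        B12 = magnetic_field(mesh, J1 + 2 * J2, obs)
        assert np.allclose(
            B12,
            magnetic_field(mesh, J1, obs) + 2 * magnetic_field(mesh, J2, obs),
            rtol=1e-12,
            atol=1e-25,
        )


class TestImpressedCurrent:
    def test_uniform_vm_no_source(self, cond):
        mesh = spherical_shell_mesh(0.15, 0.16, 1, 2)
        tf = TensorField(
            lambda r: us.spherical_fiber_direction(r, 0.0),
            cond.sigma_il,
            cond.sigma_it,
        )
        Js = impressed_current(mesh, np.full(mesh.num_nodes, -0.056), tf)
        assert np.max(np.abs(Js)) < 1e-12

    def test_gradient_along_fiber_scaled_by_sigma_il(self, cond):
        mesh = spherical_shell_mesh(0.15, 0.16, 1, 2)
        tf = TensorField(
            lambda r: np.array([0.0, 0.0, 1.0]), cond.sigma_il, cond.sigma_it
        )
        g = 0.25  # V/m along z (the fiber direction)
        Js = impressed_current(mesh, g * mesh.points[:, 2], tf)
        expect = np.tile([0.0, 0.0, -cond.sigma_il * g], (mesh.num_cells, 1))
        assert np.allclose(Js, expect, atol=1e-10)

    def test_rotation_equivariance(self, cond):
        mesh = spherical_shell_mesh(0.15, 0.16, 1, 2)
        rng = np.random.default_rng(4)
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        a = np.array([0.0, 0.0, 1.0])
        g_vec = np.array([0.3, -0.1, 0.2])
        tf = TensorField(lambda r: a, cond.sigma_il, cond.sigma_it)
        tf_rot = TensorField(lambda r: Q @ a, cond.sigma_il, cond.sigma_it)
        Js = impressed_current(mesh, mesh.points @ g_vec, tf)
        Js_rot = impressed_current(mesh, mesh.points @ (Q @ g_vec), tf_rot)
        # rotating fibers and gradient rotates the impressed current
        assert np.allclose(Js_rot, Js @ Q.T, atol=1e-10)

    def test_anisotropy_rotates_impressed_current(self, shell_run, cond):
        """With 45-degree fibers the impressed current is rotated away from
        the propagation direction (the transverse component that drives the
        normal magnetic field)."""
        mesh = shell_run["mesh"]
        v = shell_run["v"]
        i_mid = np.searchsorted(v.times, 8.0)
        tf_i = TensorField(
            shell_run["tensor"].fiber, cond.sigma_il, cond.sigma_it
        )
        Js = impressed_current(mesh, v.values[i_mid], tf_i)
        grad = fem.gradient_of_nodal_field(mesh, v.values[i_mid])
        nJ = np.linalg.norm(Js, axis=1)
        nG = np.linalg.norm(grad, axis=1)
        mask = (nJ > 0.05 * nJ.max()) & (nG > 0.05 * nG.max())
        cosang = np.einsum("ei,ei->e", -Js, grad)[mask] / (nJ[mask] * nG[mask])
        angles = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
        assert np.median(angles) > 5.0


class TestSensors:
    def test_projection_orthogonal_and_aligned(self):
        sensors = SensorArray(
            positions=np.array([[0.2, 0, 0], [0, 0.2, 0]]),
            normals=np.array([[1.0, 0, 0], [0, 1.0, 0]]),
        )
        B = np.array([[0.0, 1e-12, 0.0], [0.0, 1e-12, 0.0]])
        out = mmg_projection(B, sensors)
        assert out[0] == 0.0
        assert out[1] == pytest.approx(1e-12)

    def test_csv_roundtrip(self, tmp_path):
        arr = SensorArray.spherical_cap((-0.03, 0, 0), 0.21, n=12)
        path = tmp_path / "sensors.csv"
        arr.to_csv(path)
        back = SensorArray.from_csv(path)
        assert np.allclose(back.positions, arr.positions)
        assert np.allclose(back.normals, arr.normals)

    def test_nonunit_normals_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            SensorArray(np.zeros((1, 3)), np.array([[0.0, 0.0, 2.0]]))
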