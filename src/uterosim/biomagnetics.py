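"""Currents and the abdominal-surface magnetic field (MMG).

The impressed (biological) current density is J_s = -G_i' grad v_m; adding
the ohmic return currents gives the total current density J, which is
divergence-free under quasi-statics.  The magnetic field outside the
sources follows from Biot–Savart volume quadrature over the element-wise
constant currents,

    B(r) = (mu0 / 4 pi) sum_e  J_e x (r - r_e) / ||r - r_e||^3  vol_e,

equivalent to solving curl(B/mu0) = J with the field vanishing at
infinity; no air-box mesh is required.  The magnetomyogram signal is the
projection of B onto the outward abdominal surface normal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import fem
from .conductivity import ConductivityModel, TensorField
from .geometry import Compartment
from .meshing import Mesh

MU0 = 4.0e-7 * np.pi

__all__ = [
    "MU0",
    "SensorArray",
    "biot_savart",
    "impressed_current",
    "total_current",
    "magnetic_field",
    "mmg_projection",
]


@dataclass
class SensorArray:
    """Sensor positions on (or near) the abdominal surface with outward
    unit normals."""

    positions: np.ndarray  # (s, 3)
    normals: np.ndarray  # (s, 3)
    ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.normals = np.atleast_2d(np.asarray(self.normals, dtype=float))
        if self.positions.shape != self.normals.shape:
            raise ValueError("positions and normals must have matching shape")
        nrm = np.linalg.norm(self.normals, axis=1)
        if not np.allclose(nrm, 1.0, atol=1e-6):
            raise ValueError("sensor normals must be unit length")
        if self.ids is None:
            self.ids = np.arange(len(self.positions))

    def __len__(self) -> int:
        return len(self.positions)

    @staticmethod
    def spherical_cap(
        center,
        radius: float,
        n: int = 37,
        axis=(1.0, 0.0, 0.0),
        half_angle_deg: float = 60.0,
    ) -> "SensorArray":
        """Deterministic sensor grid on a spherical cap (e.g. the ventral
        abdominal surface), a stand-in for a curved sensor array."""
        center = np.asarray(center, dtype=float)
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        # Fibonacci spiral over the cap
        i = np.arange(n) + 0.5
        cmin = np.cos(np.deg2rad(half_angle_deg))
        cosd = 1.0 - (1.0 - cmin) * i / n
        theta = np.arccos(cosd)
        golden = np.pi * (3.0 - np.sqrt(5.0))
        phi = golden * i
        # local frame around axis
        ref = np.array([0.0, 0.0, 1.0])
        if abs(axis @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(axis, ref)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(axis, e1)
        dirs = (
            np.outer(np.cos(theta), axis)
            + np.outer(np.sin(theta) * np.cos(phi), e1)
            + np.outer(np.sin(theta) * np.sin(phi), e2)
        )
        return SensorArray(center + radius * dirs, dirs)

    @staticmethod
    def from_csv(path) -> "SensorArray":
        data = np.genfromtxt(path, delimiter=",", names=True)
        pos = np.column_stack([data["x"], data["y"], data["z"]])
        nrm = np.column_stack([data["nx"], data["ny"], data["nz"]])
        ids = data["id"].astype(int)
        return SensorArray(pos, nrm, ids)

    def to_csv(self, path) -> None:
        arr = np.column_stack([self.ids, self.positions, self.normals])
        np.savetxt(
            path,
            arr,
            delimiter=",",
            header="id,x,y,z,nx,ny,nz",
            comments="",
        )


def impressed_current(
    mesh: Mesh, v_m: np.ndarray, Gi_field: TensorField
) -> np.ndarray:
    """Element-wise impressed current density J_s = -G_i' grad v_m (A/m²)
    on the myometrial elements; zero elsewhere."""
    m_mask = mesh.cell_labels == Compartment.M
    out = np.zeros((mesh.num_cells, mesh.dim))
    if np.any(m_mask):
        grad_v = fem.gradient_of_nodal_field(mesh, np.asarray(v_m, float), m_mask)
        Gi = np.asarray(Gi_field(mesh.cell_centroids()[m_mask]))[
            :, : mesh.dim, : mesh.dim
        ]
        out[m_mask] = -np.einsum("eij,ej->ei", Gi, grad_v)
    return out


def total_current(
    mesh: Mesh,
    v_m: np.ndarray,
    phi: np.ndarray,
    Ge_field: TensorField,
    conductivity: ConductivityModel,
    lam: float = 0.0,
) -> np.ndarray:
    """Element-wise total current density J (A/m²).

    On M: J = -G_i' grad v_m - G_M' grad phi_e with G_i' = vs G_e' and
    G_M' = (1+vs) G_e'; on A, U (and F when lambda != 0): J = -G grad phi.
    Elements with undefined potential (excluded fetus) carry zero current.
    """
    labels = mesh.cell_labels
    vs = conductivity.varsigma
    comp = conductivity.compartments
    Gi_field = Ge_field.scaled(vs)
    J = impressed_current(mesh, v_m, Gi_field)
    phi = np.asarray(phi, dtype=float)
    finite = np.isfinite(phi)
    phi_safe = np.where(finite, phi, 0.0)
    grad_phi = fem.gradient_of_nodal_field(mesh, phi_safe)
    cell_ok = finite[mesh.cells].all(axis=1)
    m_mask = labels == Compartment.M
    if np.any(m_mask):
        GM = (1.0 + vs) * np.asarray(Ge_field(mesh.cell_centroids()[m_mask]))[
            :, : mesh.dim, : mesh.dim
        ]
        J[m_mask] += -np.einsum("eij,ej->ei", GM, grad_phi[m_mask])
    for label, g in (
        (Compartment.A, comp.G_A),
        (Compartment.U, comp.G_U),
        (Compartment.F, comp.G_F if lam != 0.0 else 0.0),
    ):
        mask = (labels == label) & cell_ok
        J[mask] = -g * grad_phi[mask]
    return J


def biot_savart(
    source_points: np.ndarray,
    moments: np.ndarray,
    observation_points: np.ndarray,
) -> np.ndarray:
    """B from discrete current moments (J_e * vol_e, or I * dl), tesla.

    ``B(r) = (mu0/4pi) sum_e m_e x (r - r_e) / ||r - r_e||^3``.
    """
    src = np.atleast_2d(np.asarray(source_points, dtype=float))
    mom = np.atleast_2d(np.asarray(moments, dtype=float))
    obs = np.atleast_2d(np.asarray(observation_points, dtype=float))
    B = np.zeros((obs.shape[0], 3))
    for i, r in enumerate(obs):
        d = r[None, :] - src
        dist3 = np.linalg.norm(d, axis=1) ** 3
        B[i] = (MU0 / (4.0 * np.pi)) * (np.cross(mom, d) / dist3[:, None]).sum(axis=0)
    return B


def magnetic_field(
    mesh: Mesh,
    J_cells: np.ndarray,
    observation_points: np.ndarray,
    exclusion_radius_factor: float = 0.5,
) -> np.ndarray:
    """Biot–Savart volume quadrature of element-wise currents, tesla.

    Midpoint rule per element.  Elements whose centroid lies within
    ``exclusion_radius_factor`` element diameters of an observation point
    are skipped with a warning (singular kernel); sensors should sit
    outside the conductor or at least one element away.
    """
    obs = np.atleast_2d(np.asarray(observation_points, dtype=float))
    cent = mesh.cell_centroids()
    vols = mesh.cell_volumes()
    if mesh.dim != 3:
        raise ValueError("magnetic field quadrature requires a 3D mesh")
    J = np.asarray(J_cells, dtype=float)
    diam = vols ** (1.0 / 3.0)
    B = np.zeros((obs.shape[0], 3))
    JV = J * vols[:, None]
    skipped = 0
    for i, r in enumerate(obs):
        d = r[None, :] - cent  # (m, 3)
        dist = np.linalg.norm(d, axis=1)
        near = dist < exclusion_radius_factor * diam
        skipped += int(near.sum())
        w = np.where(near, 0.0, 1.0 / np.maximum(dist, 1e-300) ** 3)
        B[i] = (MU0 / (4.0 * np.pi)) * np.einsum(
            "e,ei->i", w, np.cross(JV, d)
        )
    if skipped:
        warnings.warn(
            f"{skipped} element contributions skipped (observation point "
            "inside or touching source elements)",
            stacklevel=2,
        )
    return B


def mmg_projection(B: np.ndarray, sensors: SensorArray) -> np.ndarray:
    """Scalar magnetomyogram per sensor: B_MMG = <B, n_A>."""
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if B.shape[0] != len(sensors):
        raise ValueError("B rows must match the sensor count")
    return np.einsum("si,si->s", B, sensors.normals)
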