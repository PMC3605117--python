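"""Quasi-static volume-conductor solve: extracellular/abdominal potentials.

Given a transmembrane potential snapshot v_m on the myometrium M, solve

    div( ((vs+1)/vs) G_e' grad phi ) = -div( G_e' grad v_m )   in M,
    div( G_A grad phi ) = 0                                    in A,
    div( G_U grad phi ) = 0                                    in U,
    (and in F with G_F when the vernix switch lambda != 0),

with continuity of phi and of normal current across the internal
interfaces (imposed by the single conforming discretization), no flux
through the abdominal surface, and no flux through the fetal surface when
lambda = 0 (vernix caseosa present).  The pure-Neumann problem is gauged by
zero mean over the abdominal surface nodes, matching differential surface
measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import fem
from .conductivity import ConductivityModel, TensorField
from .geometry import Boundary, Compartment
from .meshing import Mesh
from .monodomain import FieldSeries

__all__ = ["PotentialSolution", "VolumeConductorSystem", "solve_potentials", "solve_potential_series"]


@dataclass
class PotentialSolution:
    """Nodal potential over the conductive compartments (V).

    ``phi`` is defined on all mesh nodes; entries of nodes excluded from
    the solve (fetal interior when lambda = 0) are NaN.  ``gauge`` records
    the gauge condition.
    """

    mesh: Mesh
    phi: np.ndarray
    gauge: str


class VolumeConductorSystem:
    """Assembled and factorized interface problem, reusable across snapshots."""

    def __init__(
        self,
        mesh: Mesh,
        conductivity: ConductivityModel,
        tensor_field: TensorField,
        lam: float = 0.0,
    ) -> None:
        if mesh.dim != 3 and mesh.dim != 2:
            raise ValueError("volume conductor solve needs a 2D or 3D mesh")
        self.mesh = mesh
        self.lam = lam
        self.conductivity = conductivity
        labels = mesh.cell_labels
        comp = conductivity.compartments
        vs = conductivity.varsigma
        if vs <= 0:
            raise ValueError("varsigma must be positive for the bulk tensor")

        centroids = mesh.cell_centroids()
        d = mesh.dim
        G = np.zeros((mesh.num_cells, d, d))
        eye = np.eye(d)
        m_mask = labels == Compartment.M
        if np.any(m_mask):
            Ge = np.asarray(tensor_field(centroids[m_mask]))[:, :d, :d]
            G[m_mask] = (vs + 1.0) / vs * Ge
            self._Ge = Ge
        else:
            self._Ge = np.zeros((0, d, d))
        G[labels == Compartment.A] = comp.G_A * eye
        G[labels == Compartment.U] = comp.G_U * eye
        include_f = lam != 0.0
        if include_f:
            G[labels == Compartment.F] = comp.G_F * eye

        active_cells = m_mask | (labels == Compartment.A) | (labels == Compartment.U)
        if include_f:
            active_cells |= labels == Compartment.F
        self.active_cells = active_cells
        self.active_nodes = np.unique(mesh.cells[active_cells])
        self.m_mask = m_mask

        K = fem.stiffness_matrix(mesh, G[active_cells], cells_mask=active_cells)
        # gauge: zero mean over the abdominal-surface nodes (fall back to all
        # active nodes when the mesh has no tagged dA facets, e.g. a shell)
        da = mesh.facets[mesh.facet_labels == Boundary.dA]
        gauge_nodes = np.unique(da) if da.size else self.active_nodes
        self.gauge_nodes = gauge_nodes
        w = np.zeros(mesh.num_nodes)
        w[gauge_nodes] = 1.0 / gauge_nodes.size
        # bordered symmetric saddle system [[K, w],[w^T, 0]] on active nodes
        act = self.active_nodes
        self._act = act
        idx = -np.ones(mesh.num_nodes, dtype=int)
        idx[act] = np.arange(act.size)
        self._idx = idx
        Ka = K[act][:, act]
        wa = w[act]
        A = sp.bmat([[Ka, wa[:, None]], [wa[None, :], None]], format="csc")
        self._solve = spla.factorized(A)
        self._gauge_desc = (
            "zero mean over abdominal-surface nodes"
            if da.size
            else "zero mean over all conductive nodes"
        )

    def source_from_vm(self, v_m: np.ndarray) -> np.ndarray:
        """Load vector of -div(G_e' grad v_m): rhs_i = -int grad phi_i . G_e' grad v_m."""
        if v_m.shape[0] != self.mesh.num_nodes:
            raise ValueError("v_m layout does not match the mesh")
        grad_v = fem.gradient_of_nodal_field(self.mesh, v_m, cells_mask=self.m_mask)
        flux = np.einsum("eij,ej->ei", self._Ge, grad_v)
        # weak form: K_e v with sign such that A phi = -K_e v_m
        return fem.divergence_rhs(self.mesh, -flux, cells_mask=self.m_mask)

    def solve(self, rhs: np.ndarray) -> PotentialSolution:
        """Solve for phi given an assembled load vector (length num_nodes)."""
        b = np.concatenate([rhs[self._act], [0.0]])
        sol = self._solve(b)
        phi = np.full(self.mesh.num_nodes, np.nan)
        phi[self._act] = sol[:-1]
        return PotentialSolution(self.mesh, phi, self._gauge_desc)

    def solve_vm(self, v_m: np.ndarray) -> PotentialSolution:
        return self.solve(self.source_from_vm(v_m))


def point_dipole_load(mesh: Mesh, position, moment) -> np.ndarray:
    """FEM load vector of a point current dipole at ``position``.

    For J_s = p delta(r - r0) the weak source is rhs_i = p . grad(phi_i)(r0)
    on the element containing r0 (P1 gradients are element-wise constant).
    Used for validation against closed-form conductor solutions.
    """
    r0 = np.asarray(position, dtype=float)
    p = np.asarray(moment, dtype=float)
    grads, _ = fem.shape_gradients(mesh)
    x = mesh.cell_points()
    # barycentric coordinates of r0 in every cell: lam_k = grad_k . (r0-x0) (+1 for k=0)
    lam = np.einsum("eki,ei->ek", grads, r0[None, : mesh.dim] - x[:, 0, :])
    lam[:, 0] += 1.0
    inside = np.all(lam >= -1e-10, axis=1)
    if not np.any(inside):
        raise ValueError("dipole position outside the mesh")
    e = int(np.argmax(inside))
    rhs = np.zeros(mesh.num_nodes)
    rhs[mesh.cells[e]] = grads[e] @ p[: mesh.dim]
    return rhs


def solve_potentials(
    mesh: Mesh,
    v_m: np.ndarray,
    conductivity: ConductivityModel,
    tensor_field: TensorField,
    lam: float = 0.0,
) -> PotentialSolution:
    """One-shot elliptic solve for a single v_m snapshot."""
    sys_ = VolumeConductorSystem(mesh, conductivity, tensor_field, lam)
    return sys_.solve_vm(np.asarray(v_m, dtype=float))


def solve_potential_series(
    mesh: Mesh,
    v_series: FieldSeries,
    conductivity: ConductivityModel,
    tensor_field: TensorField,
    lam: float = 0.0,
) -> FieldSeries:
    """Snapshot-wise potentials (quasi-static: each instant independent)."""
    sys_ = VolumeConductorSystem(mesh, conductivity, tensor_field, lam)
    out = np.empty_like(np.asarray(v_series.values, dtype=float))
    for i, snap in enumerate(v_series.values):
        out[i] = sys_.solve_vm(np.asarray(snap, dtype=float)).phi
    return FieldSeries(mesh, v_series.times, out, "phi", "V")
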