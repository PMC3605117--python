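"""First-order (P1) simplicial finite-element assembly on 1D/2D/3D meshes.

Vectorized over elements with numpy; matrices are scipy.sparse CSR.  The
stiffness form is ``K_ij = sum_e vol_e (grad phi_i)^T G_e (grad phi_j)``
with a per-element (possibly anisotropic) conductivity tensor ``G_e``.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .meshing import Mesh

__all__ = [
    "shape_gradients",
    "stiffness_matrix",
    "mass_matrix",
    "lumped_mass",
    "gradient_of_nodal_field",
    "divergence_rhs",
]


def shape_gradients(mesh: Mesh, cells: np.ndarray | None = None):
    """Gradients of the barycentric shape functions.

    Returns ``(grads, vols)`` with ``grads`` of shape (m, dim+1, dim): the
    constant gradient of each vertex shape function on each simplex.
    """
    if cells is None:
        cells = mesh.cells
    x = mesh.points[cells]  # (m, d+1, d)
    d = mesh.dim
    edges = x[:, 1:, :] - x[:, :1, :]  # (m, d, d)
    det = np.linalg.det(edges) if d > 1 else edges[:, 0, 0]
    vols = np.abs(det) / {1: 1.0, 2: 2.0, 3: 6.0}[d]
    # barycentric coords lambda_k (k=1..d) satisfy edges^T lambda' = x - x0,
    # so grad lambda_k is the k-th row of inv(edges^T) = column of inv(edges)
    inv = np.linalg.inv(edges)
    grads = np.empty((x.shape[0], d + 1, d))
    grads[:, 1:, :] = np.transpose(inv, (0, 2, 1))
    grads[:, 0, :] = -grads[:, 1:, :].sum(axis=1)
    return grads, vols


def _assemble(mesh, cells, values):
    """Scatter (m, d+1, d+1) element matrices into a CSR matrix."""
    n = mesh.num_nodes
    d1 = cells.shape[1]
    rows = np.repeat(cells, d1, axis=1).ravel()
    cols = np.tile(cells, (1, d1)).ravel()
    return sp.csr_matrix((values.ravel(), (rows, cols)), shape=(n, n))


def _tensor_per_cell(mesh, conductivity, cells_mask=None):
    m = mesh.num_cells if cells_mask is None else int(np.count_nonzero(cells_mask))
    d = mesh.dim
    G = np.asarray(conductivity, dtype=float)
    if G.ndim == 0:
        return G * np.broadcast_to(np.eye(d), (m, d, d))
    if G.ndim == 1:  # scalar per cell
        return G[:, None, None] * np.eye(d)
    if G.ndim == 2:  # one tensor for all cells
        return np.broadcast_to(G, (m, d, d))
    return G


def stiffness_matrix(
    mesh: Mesh, conductivity, cells_mask: np.ndarray | None = None
) -> sp.csr_matrix:
    """Assemble ``int grad v . G grad u`` over (a subset of) elements.

    ``conductivity`` may be a scalar, a per-cell scalar array, a single
    dim×dim tensor or a per-cell (m, dim, dim) tensor field.  The matrix is
    symmetric positive semidefinite with constants in its null space.
    """
    cells = mesh.cells if cells_mask is None else mesh.cells[cells_mask]
    grads, vols = shape_gradients(mesh, cells)
    G = _tensor_per_cell(mesh, conductivity, cells_mask)
    # check SPD (eigenvalues of symmetric part)
    w = np.linalg.eigvalsh(0.5 * (G + np.transpose(G, (0, 2, 1))))
    if np.any(w[:, 0] <= 0):
        bad = int(np.argmax(w[:, 0] <= 0))
        raise ValueError(
            f"conductivity tensor not positive definite on element {bad}"
        )
    Gg = np.einsum("eij,ekj->eki", G, grads)  # G grad phi_k
    elem = np.einsum("eki,eli->ekl", grads, Gg) * vols[:, None, None]
    return _assemble(mesh, cells, elem)


def mass_matrix(mesh: Mesh, cells_mask: np.ndarray | None = None) -> sp.csr_matrix:
    """Consistent P1 mass matrix."""
    cells = mesh.cells if cells_mask is None else mesh.cells[cells_mask]
    _, vols = shape_gradients(mesh, cells)
    d1 = cells.shape[1]
    base = (np.ones((d1, d1)) + np.eye(d1)) / (d1 * (d1 + 1.0))
    elem = vols[:, None, None] * base
    return _assemble(mesh, cells, elem)


def lumped_mass(mesh: Mesh, cells_mask: np.ndarray | None = None) -> np.ndarray:
    """Row-sum lumped mass (nodal volumes), as a 1D array."""
    cells = mesh.cells if cells_mask is None else mesh.cells[cells_mask]
    _, vols = shape_gradients(mesh, cells)
    d1 = cells.shape[1]
    out = np.zeros(mesh.num_nodes)
    np.add.at(out, cells.ravel(), np.repeat(vols / d1, d1))
    return out


def gradient_of_nodal_field(
    mesh: Mesh, u: np.ndarray, cells_mask: np.ndarray | None = None
) -> np.ndarray:
    """Element-wise constant gradient of a P1 nodal field, shape (m, dim)."""
    cells = mesh.cells if cells_mask is None else mesh.cells[cells_mask]
    grads, _ = shape_gradients(mesh, cells)
    return np.einsum("eki,ek->ei", grads, u[cells])


def divergence_rhs(
    mesh: Mesh, vec_per_cell: np.ndarray, cells_mask: np.ndarray | None = None
) -> np.ndarray:
    """Weak divergence: rhs_i = -int grad phi_i . F over elements.

    For an element-wise vector field F this is the load vector of the source
    term ``-div F`` under integration by parts with no-flux boundaries.
    """
    cells = mesh.cells if cells_mask is None else mesh.cells[cells_mask]
    grads, vols = shape_gradients(mesh, cells)
    contrib = -np.einsum("eki,ei->ek", grads, vec_per_cell) * vols[:, None]
    out = np.zeros(mesh.num_nodes)
    np.add.at(out, cells.ravel(), contrib.ravel())
    return out
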