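"""Monodomain reaction–diffusion solve for the transmembrane potential.

Equation (myometrium M, no-flux boundaries, resting initial conditions):

    div( vs/(vs+1) G_e' grad v_m ) = a_m c_m dv_m/dt + a_m (J_ion - J_stim)

discretized with P1 FEM (optionally lumped mass) and IMEX time stepping:
implicit (backward-Euler) diffusion, explicit reaction, exact exponential
update of the linear recovery variable.  The diffusion system matrix is
factorized once, so each step costs one sparse triangular solve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import fem
from .fhn import PacemakerSpec
from .geometry import Compartment
from .meshing import Mesh, interval_mesh
from .params import IonicParams, SolverConfig

__all__ = [
    "FieldSeries",
    "Operators",
    "StabilityError",
    "assemble_operators",
    "run_monodomain",
    "simulate_cable_front",
]


class StabilityError(RuntimeError):
    pass


@dataclass
class FieldSeries:
    """Time-stamped nodal (or element-wise) fields on a mesh."""

    mesh: Mesh
    times: np.ndarray
    values: np.ndarray  # (T, n) or (T, n, k)
    name: str = "field"
    units: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values)
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValueError("time stamps must be strictly increasing")
        if self.values.shape[0] != self.times.size:
            raise ValueError("values first axis must match times")

    def probe(self, point) -> np.ndarray:
        """Trace at the node nearest to ``point``."""
        return self.values[:, self.nearest_node(point)]

    def nearest_node(self, point) -> int:
        p = np.atleast_1d(np.asarray(point, dtype=float))
        d2 = ((self.mesh.points - p[None, : self.mesh.points.shape[1]]) ** 2).sum(
            axis=1
        )
        return int(np.argmin(d2))

    def to_csv(self, path, probes: Sequence | None = None) -> None:
        if probes is None:
            idx = np.arange(self.values.shape[1])
        else:
            idx = [self.nearest_node(p) for p in probes]
        arr = np.column_stack([self.times] + [self.values[:, i] for i in idx])
        header = "t," + ",".join(f"node{i}" for i in idx)
        np.savetxt(path, arr, delimiter=",", header=header, comments="")


@dataclass
class Operators:
    """Discrete operators of the monodomain equation on compartment M."""

    mesh: Mesh
    mass: np.ndarray | sp.csr_matrix  # lumped (1D array) or consistent
    stiffness: sp.csr_matrix  # for vs/(vs+1) G_e'
    varsigma: float
    lumped: bool
    active: np.ndarray  # node indices of M


def assemble_operators(
    mesh: Mesh,
    conductivity,
    varsigma: float,
    params: IonicParams,
    mass_lumping: bool = True,
) -> Operators:
    """Assemble mass and stiffness for div( vs/(vs+1) G_e' grad . ).

    ``conductivity`` is the extracellular tensor description (scalar
    sigma_el for 1D cables, per-cell (m,d,d) tensors, or a TensorField
    evaluated at element centroids).  Only elements labelled M enter.
    """
    mask = mesh.cell_labels == Compartment.M
    if not np.all(mask):
        raise ValueError("monodomain operators require all elements in M")
    cond = conductivity
    if callable(cond) and not isinstance(cond, np.ndarray):
        cond = cond(mesh.cell_centroids())
    factor = varsigma / (varsigma + 1.0)
    K = fem.stiffness_matrix(mesh, cond)
    K = (factor * K).tocsr()
    if mass_lumping:
        M = fem.lumped_mass(mesh)
    else:
        M = fem.mass_matrix(mesh)
    active = np.arange(mesh.num_nodes)
    return Operators(mesh, M, K, varsigma, mass_lumping, active)


def run_monodomain(
    mesh: Mesh,
    operators: Operators,
    params: IonicParams,
    pacemakers: Sequence[PacemakerSpec],
    config: SolverConfig,
    v0: np.ndarray | None = None,
    w0: np.ndarray | None = None,
) -> tuple[FieldSeries, FieldSeries]:
    """Integrate the monodomain equation; returns (v_m, w) series.

    IMEX stepping: the diffusion term is treated implicitly, the cubic
    reaction explicitly and the recovery variable by its exact exponential
    (v_m held over the step).  Raises :class:`StabilityError` if |v_m|
    exceeds 1 V; the caller should reduce ``dt`` or refine the mesh.
    """
    p = params
    n = mesh.num_nodes
    dt = config.dt
    steps = int(round(config.t_end / dt))
    amcm = p.a_m * p.c_m

    K = operators.stiffness
    if operators.lumped:
        Mdiag = operators.mass
        A = sp.diags(amcm / dt * Mdiag) + K
        Mmul = lambda x: Mdiag * x  # noqa: E731
    else:
        Mc = operators.mass
        A = (amcm / dt) * Mc + K
        Mmul = lambda x: Mc @ x  # noqa: E731
    solve = spla.factorized(A.tocsc())

    v = np.full(n, p.v_mr) if v0 is None else np.asarray(v0, dtype=float).copy()
    w_rest = (p.beta * p.v_mr + p.delta) / p.gamma
    w = np.full(n, w_rest) if w0 is None else np.asarray(w0, dtype=float).copy()
    pts = mesh.points if mesh.dim > 1 else np.column_stack([mesh.points[:, 0]])

    out_t = [0.0]
    out_v = [v.copy()]
    out_w = [w.copy()]
    decay = np.exp(-p.eps2 * p.gamma * dt)
    for i in range(steps):
        t = i * dt
        cubic = p.k * (v - p.v1) * (p.v2 - v) * (v - p.v3)
        j_ion = -(cubic - w) / p.eps1  # A/m^2 (membrane-referred)
        j_stim = np.zeros(n)
        for pm in pacemakers:
            j_stim += pm.nu * np.asarray(pm.support(pts, t), dtype=float)
        j_stim /= p.eps1
        rhs = Mmul(amcm / dt * v + p.a_m * (-j_ion + j_stim))
        v = solve(rhs)
        if not np.all(np.isfinite(v)) or np.max(np.abs(v)) > 1.0:
            raise StabilityError(
                f"monodomain solve unstable at t={t + dt:.3f} s "
                "(|v_m| > 1 V); reduce dt or refine the mesh"
            )
        # exact update of w' = eps2 (beta v - gamma w + delta) at frozen v
        w_inf = (p.beta * v + p.delta) / p.gamma
        w = w_inf + (w - w_inf) * decay
        if (i + 1) % config.output_stride == 0 or i == steps - 1:
            out_t.append((i + 1) * dt)
            out_v.append(v.copy())
            out_w.append(w.copy())
    vs = FieldSeries(mesh, np.array(out_t), np.array(out_v), "v_m", "V")
    ws = FieldSeries(mesh, np.array(out_t), np.array(out_w), "w", "V")
    return vs, ws


def simulate_cable_front(
    params: IonicParams,
    sigma_el: float,
    varsigma: float,
    length: float = 0.2,
    h: float = 5.0e-4,
    dt: float = 0.01,
    t_end: float | None = None,
    stim_frac: float = 0.05,
    nu: float = 2.0,
    stim_dur: float = 0.1,
    output_stride: int = 5,
) -> FieldSeries:
    """Convenience driver: end-stimulated 1D cable along the fiber direction.

    Returns the v_m series.  ``t_end`` defaults to the time for the analytic
    front to cross the cable plus the action-potential duration margin.
    """
    from .conductivity import analytic_front_speed

    mesh = interval_mesh(length, h)
    ops = assemble_operators(mesh, sigma_el, varsigma, params)
    if t_end is None:
        c_est = max(analytic_front_speed(varsigma, params, sigma_el), 1e-4)
        t_end = length / c_est + 80.0
    pm = PacemakerSpec.interval(
        nu=nu, t_on=0.0, t_off=stim_dur, x_max=stim_frac * length
    )
    cfg = SolverConfig(dt=dt, t_end=t_end, output_stride=output_stride)
    v_series, _ = run_monodomain(mesh, ops, params, [pm], cfg)
    return v_series
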