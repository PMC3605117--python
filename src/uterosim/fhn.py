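"""Modified FitzHugh–Nagumo ionic model of the uterine myocyte.

The model is a two-variable excitable system producing the plateau-type
action potential of the pregnant human myometrium: a cubic "fast" current
in the transmembrane potential v_m and a slow linear recovery variable w,

    J_ion = -(1/eps1) [ k (v_m - v1)(v2 - v_m)(v_m - v3) - w ],
    dw/dt = eps2 (beta v_m - gamma w + delta).

``J_ion`` (and the pacemaker drive ``J_stim``) are membrane-referred current
densities in A/m²; the tissue balance multiplies them by the
surface-to-volume ratio ``a_m`` to obtain A/m³, so the space-clamped (0D)
balance reads

    c_m dv_m/dt = -J_ion + J_stim,

with the a_m factors cancelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .params import IonicParams, IonicState, surface_to_volume

__all__ = [
    "surface_to_volume",
    "PacemakerSpec",
    "ionic_current",
    "recovery_rate",
    "stimulus_current",
    "nullcline_fixed_points",
    "resting_state",
    "integrate_space_clamped",
    "Trajectory",
    "NonExcitableError",
    "IntegrationError",
]


class NonExcitableError(ValueError):
    """The fixed-point cubic has complex roots (non-excitable parameters)."""


class IntegrationError(RuntimeError):
    """The 0D integration became unstable."""


@dataclass(frozen=True)
class PacemakerSpec:
    """A pacemaker region: amplitude ``nu`` (V) and spatio-temporal support.

    ``support(r, t)`` maps positions ``r`` of shape (..., dim) and a scalar
    time to values in [0, 1].
    """

    nu: float
    support: Callable[[np.ndarray, float], np.ndarray]

    @staticmethod
    def fundus_cap(
        nu: float = 2.0,
        t_on: float = 0.0,
        t_off: float = 0.1,
        r_min: float = 0.15,
        r_max: float = 0.16,
        z_min: float = 0.15,
    ) -> "PacemakerSpec":
        """The Results example pacemaker: a polar cap of the uterine shell,
        0.15 <= ||r|| <= 0.16 and z >= 0.15, active for 0 <= t <= 0.1 s."""

        def support(r: np.ndarray, t: float) -> np.ndarray:
            r = np.asarray(r, dtype=float)
            nrm = np.linalg.norm(r, axis=-1)
            inside = (nrm >= r_min) & (nrm <= r_max) & (r[..., -1] >= z_min)
            return np.where(inside & (t_on <= t <= t_off), 1.0, 0.0)

        return PacemakerSpec(nu=nu, support=support)

    @staticmethod
    def interval(
        nu: float = 2.0,
        t_on: float = 0.0,
        t_off: float = 0.1,
        x_min: float = -math.inf,
        x_max: float = math.inf,
    ) -> "PacemakerSpec":
        """A pacemaker on a coordinate slab (end stimulus of a 1D cable)."""

        def support(r: np.ndarray, t: float) -> np.ndarray:
            r = np.asarray(r, dtype=float)
            x = r[..., 0]
            inside = (x >= x_min) & (x <= x_max)
            return np.where(inside & (t_on <= t <= t_off), 1.0, 0.0)

        return PacemakerSpec(nu=nu, support=support)


def ionic_current(state: IonicState, params: IonicParams) -> np.ndarray | float:
    """Ionic (membrane) current density J_ion, A/m².

    Returns ``-(1/eps1)[k (v-v1)(v2-v)(v-v3) - w]``; multiply by ``a_m`` for
    the volume current density used in the tissue equations.
    """
    v, w = state.v_m, state.w
    p = params
    cubic = p.k * (v - p.v1) * (p.v2 - v) * (v - p.v3)
    return -(cubic - w) / p.eps1


def recovery_rate(state: IonicState, params: IonicParams) -> np.ndarray | float:
    """Time derivative of the recovery variable, V/s."""
    p = params
    return p.eps2 * (p.beta * state.v_m - p.gamma * state.w + p.delta)


def stimulus_current(
    position: np.ndarray,
    time: float,
    pacemakers: Sequence[PacemakerSpec],
    params: IonicParams,
) -> np.ndarray | float:
    """Pacemaker stimulus J_stim = (1/eps1) sum_i nu_i h_i(r, t), A/m².

    Additive over pacemakers; each support h_i has range [0, 1].
    """
    position = np.asarray(position, dtype=float)
    total = np.zeros(position.shape[:-1]) if position.ndim > 1 else 0.0
    for pm in pacemakers:
        h = pm.support(position, time)
        if np.any(h < -1e-12) or np.any(h > 1 + 1e-12):
            raise ValueError("pacemaker support must take values in [0, 1]")
        total = total + pm.nu * h
    return total / params.eps1


def _fixed_point_cubic(params: IonicParams) -> np.ndarray:
    """Monic coefficients of (v-v1)(v-v2)(v-v3) + (beta v_mr + delta)/(k gamma)."""
    p = params
    coeffs = np.poly([p.v1, p.v2, p.v3])
    coeffs[3] += (p.beta * p.v_mr + p.delta) / (p.k * p.gamma)
    return coeffs


def nullcline_fixed_points(params: IonicParams) -> np.ndarray:
    """Roots v1* < v2* < v3* of the fast-subsystem fixed-point cubic.

    With the recovery variable frozen on its nullcline at rest,
    w = (beta v_mr + delta)/gamma, the zeros of J_ion solve

        (v - v1)(v2 - v)(v - v3) = (beta v_mr + delta)/(k gamma).

    The outer roots are the resting and excited branches of the cubic
    nullcline; the middle root is the excitation threshold.  Raises
    :class:`NonExcitableError` if the cubic has complex roots.
    """
    if params.gamma == 0:
        raise ValueError("gamma must be nonzero")
    coeffs = _fixed_point_cubic(params)
    # discriminant of the monic cubic v^3 + b v^2 + c v + d
    b, c, d = coeffs[1], coeffs[2], coeffs[3]
    disc = (
        18.0 * b * c * d - 4.0 * b**3 * d + b**2 * c**2 - 4.0 * c**3 - 27.0 * d**2
    )
    if disc < 0:
        raise NonExcitableError(
            f"fixed-point cubic has complex roots (discriminant {disc:.3e} < 0); "
            "the parameterization is not excitable"
        )
    roots = np.sort(np.roots(coeffs).real)
    # polish by Newton on the monic cubic
    for _ in range(3):
        f = np.polyval(coeffs, roots)
        df = np.polyval(np.polyder(coeffs), roots)
        roots = roots - np.where(df != 0, f / df, 0.0)
    roots = np.sort(roots)
    scale = max(abs(coeffs).max(), 1.0)
    if np.any(np.abs(np.polyval(coeffs, roots)) > 1e-12 * scale):
        raise NonExcitableError("root polishing failed to converge")
    return roots


def resting_state(params: IonicParams) -> IonicState:
    """Initial conditions: v_m = v_mr, w on its nullcline at rest."""
    if params.gamma == 0:
        raise ValueError("gamma must be nonzero")
    w0 = (params.beta * params.v_mr + params.delta) / params.gamma
    return IonicState(v_m=params.v_mr, w=w0)


@dataclass
class Trajectory:
    """A 0D time series of the ionic state."""

    t: np.ndarray
    v_m: np.ndarray
    w: np.ndarray

    def to_csv(self, path) -> None:
        arr = np.column_stack([self.t, self.v_m, self.w])
        np.savetxt(path, arr, delimiter=",", header="t,v_m,w", comments="")


def _rhs(params: IonicParams, drive: Callable[[float], float]):
    p = params

    def rhs(t, y):
        v, w = y
        cubic = p.k * (v - p.v1) * (p.v2 - v) * (v - p.v3)
        j_ion = -(cubic - w) / p.eps1
        dv = (-j_ion + drive(t)) / p.c_m
        dw = p.eps2 * (p.beta * v - p.gamma * w + p.delta)
        return (dv, dw)

    return rhs


def integrate_space_clamped(
    params: IonicParams,
    drive: Callable[[float], float] | None = None,
    t_span: tuple[float, float] = (0.0, 100.0),
    dt: float = 1.0e-3,
    method: str = "bdf",
    t_eval: np.ndarray | None = None,
    y0: IonicState | None = None,
) -> Trajectory:
    """Integrate the space-clamped (0D) myocyte from the resting state.

    ``drive(t)`` is the stimulus current J_stim in A/m² (e.g. built from
    :func:`stimulus_current` at a fixed position).  ``method`` is ``"bdf"``
    (stiff multistep, adaptive within ``dt``-bounded steps; the default) or
    ``"midpoint"`` (fixed-step implicit midpoint, useful for convergence
    studies).  Raises :class:`IntegrationError` if |v_m| exceeds 1 V.
    """
    if drive is None:
        drive = lambda t: 0.0  # noqa: E731
    if dt <= 0:
        raise ValueError("dt must be positive")
    t0, t1 = t_span
    if not (np.isfinite(t0) and np.isfinite(t1) and t1 > t0):
        raise ValueError("t_span must be finite and increasing")
    state0 = resting_state(params) if y0 is None else y0
    y = np.array([state0.v_m, state0.w], dtype=float)

    if method == "bdf":
        if t_eval is None:
            nt = max(1, int(round((t1 - t0) / dt)))
            t_eval = np.linspace(t0, t1, nt + 1)
        sol = solve_ivp(
            _rhs(params, drive),
            (t0, t1),
            y,
            method="BDF",
            t_eval=t_eval,
            max_step=max(dt, 0.05),
            rtol=1e-8,
            atol=1e-10,
        )
        if not sol.success:
            raise IntegrationError(sol.message)
        v, w = sol.y
        if np.max(np.abs(v)) > 1.0:
            raise IntegrationError(
                "0D integration unstable (|v_m| > 1 V); reduce dt"
            )
        return Trajectory(t=sol.t, v_m=v, w=w)

    if method != "midpoint":
        raise ValueError(f"unknown method {method!r}")

    rhs = _rhs(params, drive)
    n = int(round((t1 - t0) / dt))
    ts = t0 + dt * np.arange(n + 1)
    out = np.empty((n + 1, 2))
    out[0] = y
    for i in range(n):
        tm = ts[i] + 0.5 * dt
        # implicit midpoint: y1 = y0 + dt f((y0+y1)/2, tm); Newton in ym
        ym = y + 0.5 * dt * np.asarray(rhs(ts[i], y))
        for _ in range(8):
            f = np.asarray(rhs(tm, ym))
            g = ym - y - 0.5 * dt * f
            if abs(g[0]) + abs(g[1]) < 1e-14:
                break
            # analytic Jacobian of rhs
            p = params
            v = ym[0]
            dcub = p.k * (
                (p.v2 - v) * (v - p.v3) - (v - p.v1) * (v - p.v3) + (v - p.v1) * (p.v2 - v)
            )
            j11 = dcub / (p.eps1 * p.c_m)
            j12 = -1.0 / (p.eps1 * p.c_m)
            j21 = p.eps2 * p.beta
            j22 = -p.eps2 * p.gamma
            a11 = 1.0 - 0.5 * dt * j11
            a12 = -0.5 * dt * j12
            a21 = -0.5 * dt * j21
            a22 = 1.0 - 0.5 * dt * j22
            det = a11 * a22 - a12 * a21
            ym = ym - np.array(
                [(a22 * g[0] - a12 * g[1]) / det, (-a21 * g[0] + a11 * g[1]) / det]
            )
        y = 2.0 * ym - y
        if abs(y[0]) > 1.0:
            raise IntegrationError(
                f"0D integration unstable at t={ts[i+1]:.3f} (|v_m| > 1 V); reduce dt"
            )
        out[i + 1] = y
    return Trajectory(t=ts, v_m=out[:, 0], w=out[:, 1])
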