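"""Myometrial conductivity design: Archie's law, the myocyte grid model,
the equal-anisotropy ratio, and cylindrically symmetric tensor fields.

The extracellular medium conductivity is obtained from the bulk myometrium
conductivity by Archie's law, sigma_e~ = sigma_M / (1-p)^m, then reduced to
longitudinal/transverse effective values by the fraction of a cubical cell
grid blocked by the (insulating) myocytes.  Intracellular tensors follow
from the equal-anisotropy assumption G_i' = varsigma * G_e', with varsigma
calibrated so the monodomain traveling front matches a reported propagation
speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .fhn import nullcline_fixed_points
from .params import CompartmentConductivities, IonicParams, MyocyteGeometry

__all__ = [
    "ConductivityModel",
    "TensorField",
    "CalibrationError",
    "archie_extracellular",
    "grid_conductivities",
    "anisotropy_ratio",
    "eps1_admissible_interval",
    "analytic_front_speed",
    "calibrate_varsigma_numeric",
    "assemble_tensor_field",
    "design_conductivities",
]


class CalibrationError(ValueError):
    pass


def archie_extracellular(sigma_M: float, p: float, m: float) -> float:
    """Archie's law: extracellular conductivity from the bulk value.

    ``sigma_e~ = sigma_M / (1 - p)^m`` with ``p`` the volume fraction of
    myocytes plus collagenous fibers and ``m`` the cementation factor.
    """
    if not 0 <= p < 1:
        raise ValueError("volume fraction p must satisfy 0 <= p < 1")
    if m <= 0 or sigma_M <= 0:
        raise ValueError("require m > 0 and sigma_M > 0")
    return sigma_M / (1.0 - p) ** m


def grid_conductivities(
    sigma_e_tilde: float, geom: MyocyteGeometry
) -> tuple[float, float]:
    """Longitudinal/transverse extracellular conductivities of the grid model.

    Myocytes are long cylinders on a cubical grid of pitch d_T x d_T x l_T:

        sigma_el = sigma_e~ (1 - pi d_cell^2 / (4 d_T^2))
        sigma_et = sigma_e~ (1 - d_cell l_cell / (d_T l_T))
    """
    if sigma_e_tilde <= 0:
        raise ValueError("sigma_e_tilde must be positive")
    frac_l = math.pi * geom.d_cell**2 / (4.0 * geom.d_T**2)
    frac_t = geom.d_cell * geom.l_cell / (geom.d_T * geom.l_T)
    if frac_l >= 1 or frac_t >= 1:
        raise ValueError("myocytes overlap: blocked area/length fraction >= 1")
    return sigma_e_tilde * (1.0 - frac_l), sigma_e_tilde * (1.0 - frac_t)


def _roots_spread(roots: np.ndarray) -> float:
    r1, r2, r3 = np.sort(np.asarray(roots, dtype=float))
    return r1 - 2.0 * r2 + r3


def eps1_admissible_interval(
    c: float, params: IonicParams, sigma_el: float, roots: np.ndarray | None = None
) -> tuple[float, float]:
    """Open interval of eps1 values for which varsigma >= 0 at speed ``c``."""
    if roots is None:
        roots = nullcline_fixed_points(params)
    S = _roots_spread(roots)
    upper = sigma_el * params.k * S**2 / (2.0 * c**2 * params.a_m * params.c_m**2)
    return (0.0, upper)


def anisotropy_ratio(
    c: float,
    params: IonicParams,
    sigma_el: float,
    roots: np.ndarray | None = None,
) -> float:
    """Equal-anisotropy ratio reproducing front speed ``c`` (m/s).

    Derived from the traveling-wave ansatz v_m(xi.r - c t) applied to the
    monodomain equation along the fiber: with the recovery variable frozen
    at rest the reaction is the cubic with roots v1* < v2* < v3*, and the
    bistable-front speed is

        c = sqrt(Atilde * D / 2) * (v1* - 2 v2* + v3*),
        D = (vs/(1+vs)) sigma_el / (a_m c_m),  Atilde = k / (eps1 c_m),

    giving vs = g(x), g(x) = x/(1-x), with

        x = 2 c^2 eps1 a_m c_m^2 / (sigma_el k (v1* - 2 v2* + v3*)^2).

    Raises :class:`CalibrationError` (reporting the admissible eps1
    interval) if x >= 1, i.e. the requested speed exceeds the model's
    maximum attainable front speed.
    """
    if roots is None:
        roots = nullcline_fixed_points(params)
    S = _roots_spread(roots)
    x = (
        2.0
        * c**2
        * params.eps1
        * params.a_m
        * params.c_m**2
        / (sigma_el * params.k * S**2)
    )
    if x >= 1.0:
        lo, hi = eps1_admissible_interval(c, params, sigma_el, roots)
        raise CalibrationError(
            f"no nonnegative anisotropy ratio at speed c={c} m/s: requires "
            f"eps1 in ({lo:.4g}, {hi:.4g}) Ohm m^2, got {params.eps1}"
        )
    return x / (1.0 - x)


def analytic_front_speed(
    varsigma: float,
    params: IonicParams,
    sigma_el: float,
    roots: np.ndarray | None = None,
) -> float:
    """Closed-form monodomain front speed (m/s) at a given anisotropy ratio."""
    if roots is None:
        roots = nullcline_fixed_points(params)
    S = _roots_spread(roots)
    sig_eff = varsigma / (1.0 + varsigma) * sigma_el
    D = sig_eff / (params.a_m * params.c_m)
    A = params.k / (params.eps1 * params.c_m)
    return math.sqrt(A * D / 2.0) * S


def calibrate_varsigma_numeric(
    c_target: float,
    params: IonicParams,
    sigma_el: float,
    cable_length: float = 0.1,
    h: float = 5.0e-4,
    dt: float = 0.01,
    tol: float = 0.01,
    vs_bracket: tuple[float, float] = (1e-3, 50.0),
) -> float:
    """Bisection on varsigma so the measured 1D cable front speed equals
    ``c_target`` (independent numerical counterpart of
    :func:`anisotropy_ratio`).

    Raises :class:`CalibrationError` if the target exceeds the speed
    measured at the upper bracket end.
    """
    from .metrics import front_speed_1d
    from .monodomain import simulate_cable_front

    def speed(vs: float) -> float:
        series = simulate_cable_front(
            params, sigma_el, vs, length=cable_length, h=h, dt=dt
        )
        return front_speed_1d(series)[0]

    lo, hi = vs_bracket
    s_hi = speed(hi)
    if s_hi < c_target:
        raise CalibrationError(
            f"target speed {c_target} m/s exceeds the attainable maximum "
            f"(measured {s_hi:.4g} m/s at varsigma={hi})"
        )
    s_lo = speed(lo)
    if s_lo > c_target:
        raise CalibrationError("target speed below the lower bracket speed")
    while hi - lo > tol * max(1.0, lo):
        mid = 0.5 * (lo + hi)
        if speed(mid) < c_target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class ConductivityModel:
    """Full conductivity description of the volume conductor."""

    sigma_M: float = 0.5
    p: float = 0.6
    m: float = 4.0 / 3.0
    sigma_e_tilde: float = 0.0
    sigma_el: float = 0.0
    sigma_et: float = 0.0
    varsigma: float = 0.8
    compartments: CompartmentConductivities = CompartmentConductivities()

    def __post_init__(self) -> None:
        for name in ("sigma_M", "sigma_e_tilde", "sigma_el", "sigma_et"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.varsigma < 0:
            raise ValueError("varsigma must be nonnegative")
        if self.sigma_el and self.sigma_et and not self.sigma_el > self.sigma_et:
            raise ValueError("expect sigma_el > sigma_et for cylinder packing")

    @property
    def sigma_il(self) -> float:
        return self.varsigma * self.sigma_el

    @property
    def sigma_it(self) -> float:
        return self.varsigma * self.sigma_et


def design_conductivities(
    geom: MyocyteGeometry = MyocyteGeometry(),
    sigma_M: float = 0.5,
    p: float = 0.6,
    m: float = 4.0 / 3.0,
    varsigma: float | None = 0.8,
    c: float | None = None,
    params: IonicParams | None = None,
    compartments: CompartmentConductivities = CompartmentConductivities(),
) -> ConductivityModel:
    """Run the full design chain Archie -> grid -> anisotropy ratio.

    If ``varsigma`` is None it is calibrated from the target speed ``c`` via
    :func:`anisotropy_ratio` (requires ``params``).
    """
    se = archie_extracellular(sigma_M, p, m)
    sel, set_ = grid_conductivities(se, geom)
    if varsigma is None:
        if c is None or params is None:
            raise ValueError("calibrating varsigma requires c and params")
        varsigma = anisotropy_ratio(c, params, sel)
    return ConductivityModel(
        sigma_M=sigma_M,
        p=p,
        m=m,
        sigma_e_tilde=se,
        sigma_el=sel,
        sigma_et=set_,
        varsigma=varsigma,
        compartments=compartments,
    )


class TensorField:
    """Cylindrically symmetric conductivity tensor field.

    ``G(r) = (sigma_l - sigma_t) a3(r) a3(r)^T + sigma_t I`` with ``a3`` the
    unit fiber direction (or 0, yielding isotropy sigma_t I).
    """

    def __init__(
        self,
        fiber: Callable[[np.ndarray], np.ndarray],
        sigma_l: float,
        sigma_t: float,
    ) -> None:
        if sigma_l <= 0 or sigma_t <= 0:
            raise ValueError("conductivities must be positive")
        self.fiber = fiber
        self.sigma_l = float(sigma_l)
        self.sigma_t = float(sigma_t)

    def fiber_at(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.array([self.fiber(p) for p in pts], dtype=float)
        nrm = np.linalg.norm(out, axis=-1)
        ok = np.isclose(nrm, 1.0, atol=1e-8) | np.isclose(nrm, 0.0, atol=1e-12)
        if not np.all(ok):
            bad = int(np.argmax(~ok))
            raise ValueError(
                f"fiber field must be unit or zero; ||a3||={nrm[bad]:.6g} at "
                f"point {pts[bad]}"
            )
        return out

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        a3 = self.fiber_at(pts)
        eye = np.eye(pts.shape[-1])
        G = (self.sigma_l - self.sigma_t) * np.einsum(
            "ni,nj->nij", a3, a3
        ) + self.sigma_t * eye
        return G if points.ndim > 1 else G[0]

    def scaled(self, factor: float) -> "TensorField":
        return TensorField(self.fiber, factor * self.sigma_l, factor * self.sigma_t)


def assemble_tensor_field(
    fiber: Callable[[np.ndarray], np.ndarray], sigma_l: float, sigma_t: float
) -> TensorField:
    """Build the tensor field G'(r) from a fiber direction field."""
    return TensorField(fiber, sigma_l, sigma_t)
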