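"""Parameter containers for the uterine forward model.

All quantities are SI: meters, seconds, volts, siemens/farads per meter.
The default constructors carry the term-pregnancy parameter set used in the
numerical example the package reproduces (human myometrium at term).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np

__all__ = [
    "IonicParams",
    "IonicState",
    "MyocyteGeometry",
    "CompartmentConductivities",
    "GeometryConfig",
    "SolverConfig",
    "surface_to_volume",
]


def surface_to_volume(d_cell: float, l_cell: float) -> float:
    """Surface-area to volume ratio of a closed cylindrical myocyte, 1/m.

    For a cylinder of diameter ``d_cell`` and length ``l_cell``::

        a_m = (pi d l + 2 pi d^2/4) / (pi d^2/4 l) = 4/d + 2/l
    """
    if d_cell <= 0 or l_cell <= 0:
        raise ValueError("cell dimensions must be positive")
    return 4.0 / d_cell + 2.0 / l_cell


@dataclass(frozen=True)
class IonicParams:
    """Constants of the plateau-type FitzHugh–Nagumo ionic model.

    ``eps1`` (Ω·m²) sets the sharpness of the action-potential edges (it is a
    membrane resistivity: the smaller, the steeper the upstroke), ``eps2``
    (1/s) the recovery rate and hence the plateau duration.  ``v1 > v2 > v3``
    (V) and ``k`` (1/V²) shape the cubic ionic current; ``beta``, ``gamma``,
    ``delta`` the linear recovery dynamics.  ``c_m`` is the membrane
    capacitance per unit area (F/m²), ``a_m`` the membrane surface-to-volume
    ratio (1/m) and ``v_mr`` the resting transmembrane potential (V).

    Note on units: the cubic/recovery expressions evaluate to membrane
    current densities (A/m²); the tissue-level balance multiplies them by
    ``a_m`` to obtain volume current densities (A/m³).  See
    :func:`uterosim.fhn.ionic_current`.
    """

    eps1: float = 200.0
    eps2: float = 0.09
    k: float = 1.0e4
    v1: float = -0.02
    v2: float = -0.04
    v3: float = -0.065
    delta: float = 0.052
    gamma: float = 0.1
    beta: float = 1.0
    c_m: float = 0.01
    a_m: float = surface_to_volume(7.0e-6, 450.0e-6)
    v_mr: float = -0.056

    def __post_init__(self) -> None:
        if self.eps1 <= 0 or self.eps2 <= 0:
            raise ValueError("eps1 and eps2 must be positive")
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.c_m <= 0 or self.a_m <= 0:
            raise ValueError("c_m and a_m must be positive")
        if not (self.v3 < self.v2 < self.v1):
            raise ValueError("require v3 < v2 < v1 (ordering of the plateau cubic)")


@dataclass
class IonicState:
    """Pointwise (or nodal-array) state of the ionic model: v_m and w, volts."""

    v_m: np.ndarray | float
    w: np.ndarray | float

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.v_m)) and np.all(np.isfinite(self.w))):
            raise ValueError("ionic state must be finite")


@dataclass(frozen=True)
class MyocyteGeometry:
    """Cylindrical myocyte dimensions and extracellular gap half-spacing (m).

    The grid model places cells on a cubical lattice of pitch
    ``d_T = d_cell + 2*delta_e`` across and ``l_T = l_cell + 2*delta_e``
    along the fiber.
    """

    d_cell: float = 7.0e-6
    l_cell: float = 450.0e-6
    delta_e: float = 0.5e-6

    def __post_init__(self) -> None:
        if min(self.d_cell, self.l_cell, self.delta_e) <= 0:
            raise ValueError("myocyte dimensions must be positive")
        if self.l_cell / self.d_cell < 10:
            import warnings

            warnings.warn(
                "myocyte aspect ratio l_cell/d_cell < 10; the long-cylinder "
                "grid-conductivity model may be inaccurate",
                stacklevel=2,
            )

    @property
    def d_T(self) -> float:
        return self.d_cell + 2.0 * self.delta_e

    @property
    def l_T(self) -> float:
        return self.l_cell + 2.0 * self.delta_e

    @property
    def a_m(self) -> float:
        return surface_to_volume(self.d_cell, self.l_cell)


@dataclass(frozen=True)
class CompartmentConductivities:
    """Isotropic conductivities (S/m) of abdomen, amniotic cavity and fetus."""

    G_A: float = 0.2
    G_U: float = 1.74
    G_F: float = 0.2

    def __post_init__(self) -> None:
        if min(self.G_A, self.G_U, self.G_F) <= 0:
            raise ValueError("compartment conductivities must be positive")


@dataclass(frozen=True)
class GeometryConfig:
    """Four-compartment spherical volume-conductor geometry (meters).

    The myometrium is the spherical shell
    ``r_myo_outer - wall_thickness < ||r|| < r_myo_outer`` centred at the
    origin; the fetus the concentric ball of radius ``r_fetus``; the abdomen
    the ball of radius ``r_abdomen`` centred at ``abdomen_offset``.
    ``lambda_vernix`` switches the fetal boundary between insulating (0,
    vernix caseosa present) and conductive (nonzero).
    """

    r_myo_outer: float = 0.16
    wall_thickness: float = 0.01
    r_fetus: float = 0.12
    r_abdomen: float = 0.21
    abdomen_offset: Tuple[float, float, float] = (-0.03, 0.0, 0.0)
    lambda_vernix: float = 0.0

    def __post_init__(self) -> None:
        if self.wall_thickness <= 0:
            raise ValueError("wall_thickness must be positive")
        r_in = self.r_myo_outer - self.wall_thickness
        if not self.r_fetus < r_in:
            raise ValueError(
                f"fetal sphere pierces the uterine wall: require r_fetus "
                f"({self.r_fetus}) < r_myo_outer - wall_thickness ({r_in})"
            )
        c = np.linalg.norm(self.abdomen_offset)
        # nearest point of the abdominal sphere along any ray from the origin
        if self.r_abdomen <= c:
            raise ValueError("abdominal sphere does not contain the origin")
        if self.r_abdomen - c <= self.r_myo_outer:
            raise ValueError(
                f"myometrium pierces abdomen: require r_abdomen - |offset| "
                f"({self.r_abdomen - c:.4g}) > r_myo_outer ({self.r_myo_outer})"
            )

    @property
    def r_myo_inner(self) -> float:
        return self.r_myo_outer - self.wall_thickness


@dataclass(frozen=True)
class SolverConfig:
    """Time-stepping controls for the monodomain solve."""

    dt: float = 0.01
    t_end: float = 100.0
    linear_tol: float = 1.0e-10
    output_stride: int = 10
    mass_lumping: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.t_end <= self.dt:
            raise ValueError("require 0 < dt < t_end")
        if self.linear_tol <= 0:
            raise ValueError("linear_tol must be positive")
        if self.output_stride < 1:
            raise ValueError("output_stride must be >= 1")


def with_params(obj, **kw):
    """Functional update helper for the frozen dataclasses above."""
    return replace(obj, **kw)
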