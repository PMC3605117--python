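"""Design of the myometrial fiber-direction field a3(r).

The uterine wall is treated as a union of closed layers given implicitly by
f(r) = const.  At each point a local orthonormal frame is built from the
layer normal n̂ = ∇f/||∇f|| and the tangent k̂ of a fundus-to-cervix "curve
of symmetry" at its perpendicular foot.  The in-layer directions t̂1 (the
meridional direction, fundus→cervix for the default branch) and
t̂2 = t̂1 × n̂ (circumferential) then give the fiber direction

    a3(r) = t̂1 cos(alpha) + t̂2 sin(alpha),

with alpha the fiber orientation angle.  At poles of the construction
(k̂ ∥ n̂) a3 = 0, encoding a point of isotropic conductivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "LocalFrame",
    "FiberFieldSpec",
    "SingularFrame",
    "local_frame",
    "fiber_direction",
    "spherical_fiber_direction",
    "axis_aligned_fiber_direction",
    "spherical_spec",
]

_EPS = 1e-12


class SingularFrame(ValueError):
    """Raised where the frame is undefined (pole of the curve of symmetry)."""


@dataclass
class LocalFrame:
    n_hat: np.ndarray
    t1_hat: np.ndarray
    t2_hat: np.ndarray
    k_hat: np.ndarray

    def gram(self) -> np.ndarray:
        B = np.stack([self.n_hat, self.t1_hat, self.t2_hat])
        return B @ B.T


@dataclass
class FiberFieldSpec:
    """Layer implicit function, curve of symmetry and orientation angle.

    ``layer_f(r)`` is scalar with nonvanishing gradient on the wall;
    ``curve(t)`` maps the parameter to points, with ``t_range`` its domain,
    parametrized from the fundus (t_range[0]) toward the cervix.  ``alpha``
    is a constant angle or a callable of position (radians).
    """

    layer_f: Callable[[np.ndarray], float]
    curve: Callable[[float], np.ndarray]
    t_range: tuple[float, float]
    alpha: float | Callable[[np.ndarray], float] = 0.0
    grad_f: Callable[[np.ndarray], np.ndarray] | None = None

    def alpha_at(self, r: np.ndarray) -> float:
        return self.alpha(r) if callable(self.alpha) else float(self.alpha)

    def gradient(self, r: np.ndarray) -> np.ndarray:
        if self.grad_f is not None:
            return np.asarray(self.grad_f(r), dtype=float)
        h = 1e-7 * max(1.0, float(np.linalg.norm(r)))
        g = np.empty(3)
        for i in range(3):
            e = np.zeros(3)
            e[i] = h
            g[i] = (self.layer_f(r + e) - self.layer_f(r - e)) / (2 * h)
        return g


def spherical_spec(radius: float, alpha: float | Callable = 0.0) -> FiberFieldSpec:
    """Spec for a spherical layer of given radius with the z-axis as curve
    of symmetry, running from the fundus (+z) to the cervix (−z)."""
    return FiberFieldSpec(
        layer_f=lambda r: float(np.linalg.norm(r)) - radius,
        grad_f=lambda r: np.asarray(r) / max(np.linalg.norm(r), _EPS),
        curve=lambda t: np.array([0.0, 0.0, -t]),
        t_range=(-2.0 * radius, 2.0 * radius),
        alpha=alpha,
    )


def _curve_tangent(spec: FiberFieldSpec, t: float) -> np.ndarray:
    h = 1e-6 * max(1.0, abs(spec.t_range[1] - spec.t_range[0]))
    d = (np.asarray(spec.curve(t + h)) - np.asarray(spec.curve(t - h))) / (2 * h)
    nrm = np.linalg.norm(d)
    if nrm < _EPS:
        raise SingularFrame("curve of symmetry has vanishing tangent")
    return d / nrm


def _nearest_foot(spec: FiberFieldSpec, r: np.ndarray, tol: float = 1e-10) -> float:
    """Parameter t0 of the perpendicular foot: <dr_C/dt, r_C(t0) - r> = 0.

    Dense sampling of the squared distance followed by golden-section
    refinement; the orthogonality residual is verified to ``tol``.
    """
    t1, t2 = spec.t_range
    ts = np.linspace(t1, t2, 257)
    pts = np.array([spec.curve(t) for t in ts])
    d2 = ((pts - r) ** 2).sum(axis=1)
    i = int(np.argmin(d2))
    lo, hi = ts[max(i - 1, 0)], ts[min(i + 1, len(ts) - 1)]

    gr = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c, d = b - gr * (b - a), a + gr * (b - a)
    fc = ((np.asarray(spec.curve(c)) - r) ** 2).sum()
    fd = ((np.asarray(spec.curve(d)) - r) ** 2).sum()
    for _ in range(200):
        if b - a < 1e-14 * max(1.0, abs(t2 - t1)):
            break
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - gr * (b - a)
            fc = ((np.asarray(spec.curve(c)) - r) ** 2).sum()
        else:
            a, c, fc = c, d, fd
            d = a + gr * (b - a)
            fd = ((np.asarray(spec.curve(d)) - r) ** 2).sum()
    t0 = 0.5 * (a + b)
    # secant refinement on the orthogonality residual g(t) = <k, r_C(t) - r>
    # (golden section alone localizes the flat quadratic minimum only to
    # ~sqrt(machine eps))
    def g(t):
        return float(_curve_tangent(spec, t) @ (np.asarray(spec.curve(t)) - r))

    ta, tb = t0 - 1e-6 * max(1.0, abs(t2 - t1)), t0
    ga, gb = g(ta), g(tb)
    for _ in range(60):
        if gb == ga:
            break
        tn = tb - gb * (tb - ta) / (gb - ga)
        if not (t1 <= tn <= t2) or abs(tn - tb) < 1e-16 * max(1.0, abs(tb)):
            tb = min(max(tn, t1), t2)
            break
        ta, ga = tb, gb
        tb, gb = tn, g(tn)
    if t1 < tb < t2:
        t0 = tb
    k = _curve_tangent(spec, t0)
    resid = float(k @ (np.asarray(spec.curve(t0)) - r))
    scale = max(np.linalg.norm(np.asarray(spec.curve(t0)) - r), 1.0)
    if abs(resid) > max(tol, 1e-8 * scale) and not np.isclose(
        np.linalg.norm(np.asarray(spec.curve(t0)) - r), 0.0
    ):
        # interior minimum must be orthogonal; endpoints may not be
        if t1 + 1e-12 < t0 < t2 - 1e-12:
            raise SingularFrame(
                f"no perpendicular foot on the curve of symmetry (residual {resid:.2e})"
            )
    return t0


def local_frame(r: np.ndarray, spec: FiberFieldSpec) -> LocalFrame:
    """Local orthonormal frame {n̂, t̂1, t̂2} at ``r``.

    Solving <t̂1, n̂> = 0, ||t̂1|| = 1 with t̂1 = beta k̂ + gamma n̂ gives
    beta = ±1/sqrt(1 - <k̂,n̂>²), gamma = ∓<k̂,n̂> beta; the branch with
    <t̂1, k̂> > 0 is chosen so that t̂1 points from the fundus toward the
    cervix when the curve is parametrized that way.  Raises
    :class:`SingularFrame` when k̂ ∥ n̂ (callers map this to a3 = 0).
    """
    r = np.asarray(r, dtype=float)
    g = spec.gradient(r)
    ng = np.linalg.norm(g)
    if ng < _EPS:
        raise SingularFrame("layer gradient vanishes")
    n_hat = g / ng
    t0 = _nearest_foot(spec, r)
    k_hat = _curve_tangent(spec, t0)
    c = float(k_hat @ n_hat)
    if 1.0 - c * c < 1e-12:
        raise SingularFrame("curve tangent parallel to layer normal (pole)")
    beta = 1.0 / np.sqrt(1.0 - c * c)
    gamma = -c * beta
    t1_hat = beta * k_hat + gamma * n_hat
    t2_hat = np.cross(t1_hat, n_hat)
    return LocalFrame(n_hat=n_hat, t1_hat=t1_hat, t2_hat=t2_hat, k_hat=k_hat)


def fiber_direction(r: np.ndarray, spec: FiberFieldSpec) -> np.ndarray:
    """Unit fiber direction a3 = t̂1 cos(alpha) + t̂2 sin(alpha), or 0 at
    singular points."""
    try:
        frame = local_frame(r, spec)
    except SingularFrame:
        return np.zeros(3)
    a = spec.alpha_at(np.asarray(r))
    return frame.t1_hat * np.cos(a) + frame.t2_hat * np.sin(a)


def spherical_fiber_direction(r: np.ndarray, alpha: float) -> np.ndarray:
    """Closed form for a spherical layer with the z-axis curve of symmetry.

    Derived from the axis-aligned construction with f = ||r|| - R:

        a3 = ( (z x cosA)/(s R) + (y sinA)/s,
               (z y cosA)/(s R) - (x sinA)/s,
               -(s/R) cosA ),  s = sqrt(x²+y²),  R = ||r||.

    Returns the zero vector on the z axis (isotropic pole).
    """
    x, y, z = np.asarray(r, dtype=float)
    s2 = x * x + y * y
    if s2 < _EPS**2:
        return np.zeros(3)
    s = np.sqrt(s2)
    R = np.sqrt(s2 + z * z)
    ca, sa = np.cos(alpha), np.sin(alpha)
    return np.array(
        [
            z * x * ca / (s * R) + y * sa / s,
            z * y * ca / (s * R) - x * sa / s,
            -s * ca / R,
        ]
    )


def axis_aligned_fiber_direction(
    r: np.ndarray, spec: FiberFieldSpec, alpha: float | None = None
) -> np.ndarray:
    """Fiber direction via the P/F-matrix construction for a curve of
    symmetry parallel to the z axis:

        a3 = (P cosA + F sinA) n̂,
        P = diag(a, a, -1/a),  F = [[0, b, 0], [-b, 0, 0], [0, 0, 0]],
        a = ∂z f / sqrt((∂x f)² + (∂y f)²),  b = ||∇f|| / sqrt((∂x f)² + (∂y f)²).

    Returns the zero vector where (∂x f)² + (∂y f)² = 0 (on-axis point).
    """
    r = np.asarray(r, dtype=float)
    g = spec.gradient(r)
    ng = np.linalg.norm(g)
    if ng < _EPS:
        return np.zeros(3)
    n_hat = g / ng
    sxy2 = g[0] ** 2 + g[1] ** 2
    if sxy2 < _EPS**2:
        return np.zeros(3)
    sxy = np.sqrt(sxy2)
    a = g[2] / sxy
    b = ng / sxy
    A = spec.alpha_at(r) if alpha is None else float(alpha)
    ca, sa = np.cos(A), np.sin(A)
    # third component -(1/a) n̂_z simplifies to -sxy/||∇f||, regular at a = 0
    Pn = np.array([a * n_hat[0], a * n_hat[1], -sxy / ng])
    Fn = np.array([b * n_hat[1], -b * n_hat[0], 0.0])
    v = Pn * ca + Fn * sa
    nrm = np.linalg.norm(v)
    return v / nrm if nrm > _EPS else np.zeros(3)
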