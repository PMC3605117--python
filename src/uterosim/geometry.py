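"""Implicit description of the four-compartment spherical volume conductor.

Compartments: F (fetus), U (amniotic cavity), M (myometrium), A (abdomen).
Interfaces: dF (fetal surface), dU (endometrium), dM (perimetrium),
dA (abdominal surface).  The fetus, cavity and myometrium are concentric
spheres about the origin; the abdominal sphere may be offset (the uterus
sits closer to the ventral than the dorsal surface).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import GeometryConfig

__all__ = ["Compartment", "Boundary", "SphericalGeometry", "build_spherical_geometry"]


class Compartment:
    F = 0
    U = 1
    M = 2
    A = 3
    NAMES = {0: "F", 1: "U", 2: "M", 3: "A"}


class Boundary:
    NONE = -1
    dF = 0
    dU = 1
    dM = 2
    dA = 3
    NAMES = {-1: "none", 0: "dF", 1: "dU", 2: "dM", 3: "dA"}


@dataclass(frozen=True)
class SphericalGeometry:
    """Signed-distance style classifiers for the four compartments."""

    config: GeometryConfig

    @property
    def abdomen_center(self) -> np.ndarray:
        return np.asarray(self.config.abdomen_offset, dtype=float)

    def radius(self, points: np.ndarray) -> np.ndarray:
        return np.linalg.norm(np.atleast_2d(points), axis=-1)

    def abdomen_distance(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        return np.linalg.norm(p - self.abdomen_center[: p.shape[-1]], axis=-1)

    def classify(self, points: np.ndarray) -> np.ndarray:
        """Compartment label per point; -1 outside the abdomen."""
        cfg = self.config
        r = self.radius(points)
        ra = self.abdomen_distance(points)
        out = np.full(r.shape, -1, dtype=int)
        out[ra <= cfg.r_abdomen] = Compartment.A
        out[r <= cfg.r_myo_outer] = Compartment.M
        out[r <= cfg.r_myo_inner] = Compartment.U
        out[r <= cfg.r_fetus] = Compartment.F
        return out

    def classify_point(self, point) -> int:
        return int(self.classify(np.atleast_2d(point))[0])

    def abdomen_ray_radius(self, directions: np.ndarray) -> np.ndarray:
        """Distance from the origin to the abdominal surface along unit rays."""
        c = self.abdomen_center
        u = np.atleast_2d(directions)
        uc = u @ c[: u.shape[-1]]
        disc = uc**2 + self.config.r_abdomen**2 - c @ c
        return uc + np.sqrt(disc)

    def interface_radius(self, boundary: int) -> float:
        cfg = self.config
        return {
            Boundary.dF: cfg.r_fetus,
            Boundary.dU: cfg.r_myo_inner,
            Boundary.dM: cfg.r_myo_outer,
        }[boundary]


def build_spherical_geometry(config: GeometryConfig) -> SphericalGeometry:
    """Validate the configuration and return the implicit geometry.

    Validation (nesting of the compartments) happens in
    :class:`~uterosim.params.GeometryConfig`; a violated inequality raises
    ``ValueError`` naming it.
    """
    return SphericalGeometry(config=config)
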