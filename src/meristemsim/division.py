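"""Cell-division rules: center mechanisms × direction mechanisms.

A division rule is a pair of mechanisms.  The *center* mechanism picks a
point inside the mother cell (its centroid, or a uniformly random interior
point); the *direction* mechanism picks an axial direction (the shortest
chord through the center — Errera's rule; a uniformly random axis; the
axis orthogonal to the cell's previous division — Sachs-like orthogonal
patterning; or the axis perpendicular to the cell's strain direction —
Hofmeister's rule).  The division plane is the straight chord through the
center along the direction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from . import geometry, mechanics
from .tissue import TissueState

logger = logging.getLogger(__name__)

__all__ = ["DivisionPlane", "DivisionRule", "RULE_NAMES", "parse_rule",
           "center_com", "center_random", "direction_shortest_path",
           "direction_random", "direction_orthogonal",
           "direction_strain_perpendicular", "make_plane"]

#: angular grid resolution for the shortest-path search
_GRID_POINTS = 720


def _canonical_axial(theta: float) -> np.ndarray:
    """Unit vector for an axial angle reduced to [0, π)."""
    th = theta % math.pi
    return np.array([math.cos(th), math.sin(th)])


@dataclass(frozen=True)
class DivisionPlane:
    """A division plane: an interior point plus an axial unit direction."""

    center: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        n = float(np.linalg.norm(d))
        if not math.isclose(n, 1.0, rel_tol=1e-9):
            raise ValueError("direction must be a unit vector")


@dataclass(frozen=True)
class DivisionRule:
    """Named combination of a direction and a center mechanism."""

    direction_mechanism: str  # ShortestPath | RandomDirection | Orthogonal | StrainPerpendicular
    center_mechanism: str     # COM | Random

    def __post_init__(self):
        if self.center_mechanism not in ("COM", "Random"):
            raise ValueError(f"unknown center mechanism {self.center_mechanism!r}")
        if self.direction_mechanism not in (
            "ShortestPath", "RandomDirection", "Orthogonal", "StrainPerpendicular"
        ):
            raise ValueError(f"unknown direction mechanism {self.direction_mechanism!r}")

    @property
    def name(self) -> str:
        return f"{self.direction_mechanism}{self.center_mechanism}"


#: rule-name strings accepted by configs and the CLI
RULE_NAMES = {
    "ShortestPathCOM": DivisionRule("ShortestPath", "COM"),
    "ShortestPathRandom": DivisionRule("ShortestPath", "Random"),
    "RandomDirectionCOM": DivisionRule("RandomDirection", "COM"),
    "RandomDirectionRandom": DivisionRule("RandomDirection", "Random"),
    "RandomRandom": DivisionRule("RandomDirection", "Random"),  # alias
    "OrthogonalCOM": DivisionRule("Orthogonal", "COM"),
    "OrthogonalRandom": DivisionRule("Orthogonal", "Random"),
    "StrainPerpendicularCOM": DivisionRule("StrainPerpendicular", "COM"),
    "StrainPerpendicularRandom": DivisionRule("StrainPerpendicular", "Random"),
}


def parse_rule(name: str) -> DivisionRule:
    try:
        return RULE_NAMES[name]
    except KeyError:
        raise ValueError(
            f"unknown division rule {name!r}; choose from {sorted(RULE_NAMES)}"
        ) from None


# -- center mechanisms -------------------------------------------------

def center_com(poly: np.ndarray) -> np.ndarray:
    """Center of mass (area centroid) of the mother cell."""
    return geometry.polygon_centroid(poly)


def center_random(poly: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Uniformly random interior point of the mother cell."""
    return geometry.random_point_in_polygon(poly, rng)


# -- direction mechanisms ----------------------------------------------

def direction_shortest_path(poly: np.ndarray, center: np.ndarray) -> np.ndarray:
    """Axial direction minimizing the chord length through ``center``.

    Coarse 720-point angular scan over [0, π) followed by bounded scalar
    refinement in the best bracket; ties break toward the smaller angle.
    """
    poly = geometry.as_polygon(poly, validate=False)
    thetas = np.linspace(0.0, math.pi, _GRID_POINTS, endpoint=False)
    lengths = geometry.chord_endpoints_grid(poly, center, thetas)
    k = int(np.argmin(lengths))
    step = math.pi / _GRID_POINTS
    lo, hi = thetas[k] - step, thetas[k] + step

    def f(th: float) -> float:
        return float(geometry.chord_endpoints_grid(poly, center, np.array([th]))[0])

    res = minimize_scalar(f, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    best = res.x if res.fun <= lengths[k] else thetas[k]
    return _canonical_axial(float(best))


def direction_random(rng: np.random.Generator) -> np.ndarray:
    """Axial direction uniform on [0, π)."""
    return _canonical_axial(rng.uniform(0.0, math.pi))


def direction_orthogonal(cell, rng: np.random.Generator) -> np.ndarray:
    """Axis orthogonal to the cell's previous division direction.

    Founder cells without a division history get a random axis.
    """
    prev = cell.last_division_direction
    if prev is None:
        logger.debug("cell %d has no division history; random direction", cell.id)
        return direction_random(rng)
    return _canonical_axial(math.atan2(prev[1], prev[0]) + math.pi / 2.0)


def direction_strain_perpendicular(t: TissueState, cell_id: int,
                                   rng: np.random.Generator,
                                   signed: bool = False,
                                   weight: str = "extension") -> np.ndarray:
    """Axis perpendicular to the cell's strain direction.

    Falls back to a random axis when the cell's walls carry no strain
    (the isotropic signal).
    """
    theta = mechanics.strain_direction(t, cell_id, signed=signed, weight=weight)
    if theta is None:
        logger.debug("cell %d isotropic; random direction", cell_id)
        return direction_random(rng)
    return _canonical_axial(theta + math.pi / 2.0)


def make_plane(t: TissueState, cell_id: int, rule: DivisionRule,
               rng: np.random.Generator,
               signed_strain: bool = False,
               strain_weight: str = "extension") -> DivisionPlane:
    """Compose the rule's center and direction mechanisms into a plane.

    For ShortestPath the direction search runs through the already-chosen
    center, so ShortestPath⊗Random minimizes the chord through the random
    point.
    """
    poly = t.cell_polygon(cell_id)
    if rule.center_mechanism == "COM":
        center = center_com(poly)
    else:
        center = center_random(poly, rng)
    dm = rule.direction_mechanism
    if dm == "ShortestPath":
        direction = direction_shortest_path(poly, center)
    elif dm == "RandomDirection":
        direction = direction_random(rng)
    elif dm == "Orthogonal":
        direction = direction_orthogonal(t.cells[cell_id], rng)
    else:
        direction = direction_strain_perpendicular(
            t, cell_id, rng, signed=signed_strain, weight=strain_weight)
    return DivisionPlane(center=center, direction=direction)
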