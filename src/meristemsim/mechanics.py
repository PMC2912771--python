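"""Overdamped spring mechanics of the tissue and its ODE right-hand side.

Vertices move with velocity proportional to the net force on them (drag
coefficient absorbed into the time unit).  Forces are linear wall springs
plus a radial body force standing in for turgor-driven internal growth.
Wall resting lengths grow under tension at a rate proportional to the
positive part of the extension, so compressed walls never shrink.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .tissue import TissueState

__all__ = ["ModelParams", "StateIndexMap", "wall_forces", "radial_forces",
           "rest_length_rates", "strain_direction", "ode_rhs"]


@dataclass(frozen=True)
class ModelParams:
    """Model constants.

    All quantities are in model units (lengths, forces and times are
    mutually consistent but arbitrary).

    spring_k
        wall spring stiffness (force per unit extension)
    growth_k
        resting-length growth rate per unit extension (1/time)
    radial_k
        magnitude of the outward radial force on each vertex
    area_threshold
        cell area above which the cell divides
    d_threshold
        minimum distance allowed between a division-created vertex and an
        existing wall junction
    radius_threshold
        centroid distance from the origin beyond which a cell is removed
    division_enabled
        master switch; ``False`` reproduces the oryzalin (no-division)
        perturbation, which also disables boundary removal
    radial_mode
        "linear" (default) applies an outward force proportional to the
        distance from the origin, which drives a uniform (isotropic)
        dilation flow; "constant" applies a fixed magnitude instead, which
        makes the expansion hoop-dominated away from the origin
    signed_strain
        if ``True`` the strain-direction statistic weighs compressed walls
        with negative weights instead of clipping them at zero
    strain_weight
        wall weight in the strain-direction statistic: "extension"
        (absolute, default) or "relative" (extension over resting length)
    """

    spring_k: float = 0.05
    growth_k: float = 0.01
    radial_k: float = 0.05
    area_threshold: float = 1.0
    d_threshold: float = 0.1
    radius_threshold: float = 7.0
    division_enabled: bool = True
    radial_mode: str = "linear"
    signed_strain: bool = False
    strain_weight: str = "extension"
    ode_rel_tol: float = 1e-6
    ode_abs_tol: float = 1e-8

    def __post_init__(self):
        for name in ("spring_k", "area_threshold", "d_threshold",
                     "radius_threshold", "ode_rel_tol", "ode_abs_tol"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("growth_k", "radial_k"):  # zero = frozen growth / no turgor
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (self.ode_rel_tol < 1 and self.ode_abs_tol < 1):
            raise ValueError("solver tolerances must lie in (0, 1)")
        if self.radial_mode not in ("constant", "linear"):
            raise ValueError("radial_mode must be 'constant' or 'linear'")
        if self.strain_weight not in ("extension", "relative"):
            raise ValueError("strain_weight must be 'extension' or 'relative'")

    def oryzalin(self) -> "ModelParams":
        """The no-division variant: same mechanics, division switched off."""
        return replace(self, division_enabled=False)


@dataclass
class StateIndexMap:
    """Flat-vector view of a tissue for the ODE solver.

    Layout: all vertex coordinates (x0, y0, x1, y1, ...) followed by all
    wall resting lengths.  Rebuilt after every topology change.
    """

    vertex_ids: list[int]
    wall_ids: list[int]
    wi1: np.ndarray  # index into the vertex list of each wall's first vertex
    wi2: np.ndarray
    n_vertices: int = field(init=False)
    n_walls: int = field(init=False)

    def __post_init__(self):
        self.n_vertices = len(self.vertex_ids)
        self.n_walls = len(self.wall_ids)

    @classmethod
    def from_tissue(cls, t: TissueState) -> "StateIndexMap":
        vids = sorted(t.vertices)
        wids = sorted(t.walls)
        vpos = {v: k for k, v in enumerate(vids)}
        wi1 = np.array([vpos[t.walls[w].v1] for w in wids], dtype=np.intp)
        wi2 = np.array([vpos[t.walls[w].v2] for w in wids], dtype=np.intp)
        return cls(vids, wids, wi1, wi2)

    def pack(self, t: TissueState) -> np.ndarray:
        y = np.empty(2 * self.n_vertices + self.n_walls)
        pos = y[: 2 * self.n_vertices].reshape(-1, 2)
        for k, vid in enumerate(self.vertex_ids):
            pos[k] = t.vertices[vid].pos
        for k, wid in enumerate(self.wall_ids):
            y[2 * self.n_vertices + k] = t.walls[wid].rest_length
        return y

    def unpack(self, y: np.ndarray, t: TissueState) -> None:
        pos = y[: 2 * self.n_vertices].reshape(-1, 2)
        for k, vid in enumerate(self.vertex_ids):
            t.vertices[vid].pos = pos[k].copy()
        for k, wid in enumerate(self.wall_ids):
            t.walls[wid].rest_length = float(y[2 * self.n_vertices + k])

    def split(self, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return y[: 2 * self.n_vertices].reshape(-1, 2), y[2 * self.n_vertices:]


def _spring_forces(pos: np.ndarray, rest: np.ndarray, wi1: np.ndarray,
                   wi2: np.ndarray, k: float) -> np.ndarray:
    """Vectorized linear-spring forces. ``pos``: (n,2); returns (n,2)."""
    d = pos[wi2] - pos[wi1]
    length = np.linalg.norm(d, axis=1)
    if np.any(length == 0.0):
        raise FloatingPointError("coincident connected vertices")
    fmag = k * (length - rest)  # >0 when stretched: pulls endpoints together
    fvec = (fmag / length)[:, None] * d
    out = np.zeros_like(pos)
    np.add.at(out, wi1, fvec)
    np.add.at(out, wi2, -fvec)
    return out


def wall_forces(t: TissueState, spring_k: float) -> dict[int, np.ndarray]:
    """Per-vertex spring forces, keyed by vertex id."""
    m = StateIndexMap.from_tissue(t)
    pos, rest = m.split(m.pack(t))
    f = _spring_forces(pos, rest, m.wi1, m.wi2, spring_k)
    return {vid: f[k].copy() for k, vid in enumerate(m.vertex_ids)}


def _radial(pos: np.ndarray, k_r: float, mode: str) -> np.ndarray:
    r = np.linalg.norm(pos, axis=1)
    if mode == "linear":
        return k_r * pos
    out = np.zeros_like(pos)
    nz = r > 0
    out[nz] = k_r * pos[nz] / r[nz, None]
    return out


def radial_forces(t: TissueState, radial_k: float, mode: str = "linear") -> dict[int, np.ndarray]:
    """Per-vertex outward radial force (zero at the origin), keyed by id."""
    m = StateIndexMap.from_tissue(t)
    pos, _ = m.split(m.pack(t))
    f = _radial(pos, radial_k, mode)
    return {vid: f[k].copy() for k, vid in enumerate(m.vertex_ids)}


def rest_length_rates(t: TissueState, growth_k: float) -> dict[int, float]:
    """Per-wall resting-length growth rate dL0/dt = k_g * max(0, l - L0)."""
    m = StateIndexMap.from_tissue(t)
    pos, rest = m.split(m.pack(t))
    length = np.linalg.norm(pos[m.wi2] - pos[m.wi1], axis=1)
    rates = growth_k * np.maximum(0.0, length - rest)
    return {wid: float(rates[k]) for k, wid in enumerate(m.wall_ids)}


def strain_direction(t: TissueState, cell_id: int, signed: bool = False,
                     weight: str = "extension") -> float | None:
    """Axial direction of the cell's wall strain, in ``[0, π)``.

    Computed by strain-weighted circular statistics on doubled wall angles:
    ``θ = ½·atan2(Σ s·sin 2φ, Σ s·cos 2φ)`` with ``φ`` the wall's axial
    direction and ``s`` its strain magnitude.  The default weight is the
    absolute extension ``l − L0``, which credits long stretched walls with
    more strain and so tracks the cell's elongation axis; ``"relative"``
    uses ``(l − L0)/L0`` instead.  Weights are clipped at zero unless
    ``signed``.  Returns ``None`` for an isotropic (all-slack) cell;
    callers fall back to a random direction.
    """
    if weight not in ("extension", "relative"):
        raise ValueError("weight must be 'extension' or 'relative'")
    cell = t.cells[cell_id]
    sin2 = cos2 = 0.0
    total = 0.0
    for wid in cell.walls:
        w = t.walls[wid]
        d = t.vertices[w.v2].pos - t.vertices[w.v1].pos
        length = math.hypot(d[0], d[1])
        if length == 0.0:
            continue
        s = length - w.rest_length
        if weight == "relative":
            s /= w.rest_length
        if not signed:
            s = max(0.0, s)
        phi = math.atan2(d[1], d[0])
        sin2 += s * math.sin(2.0 * phi)
        cos2 += s * math.cos(2.0 * phi)
        total += abs(s)
    if total == 0.0 or math.hypot(sin2, cos2) < 1e-15:
        return None
    theta = 0.5 * math.atan2(sin2, cos2) % math.pi
    if math.pi - theta < 1e-12:  # axial wrap: pi is the same axis as 0
        theta = 0.0
    return theta


def make_rhs(m: StateIndexMap, p: ModelParams):
    """Build ``f(t, y)`` for the solver, bound to a fixed index map."""
    nv2 = 2 * m.n_vertices
    wi1, wi2 = m.wi1, m.wi2

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        pos = y[:nv2].reshape(-1, 2)
        rest = y[nv2:]
        f = _spring_forces(pos, rest, wi1, wi2, p.spring_k)
        f += _radial(pos, p.radial_k, p.radial_mode)
        length = np.linalg.norm(pos[wi2] - pos[wi1], axis=1)
        drest = p.growth_k * np.maximum(0.0, length - rest)
        out = np.empty_like(y)
        out[:nv2] = f.ravel()
        out[nv2:] = drest
        if not np.all(np.isfinite(out)):
            raise FloatingPointError("non-finite force encountered")
        return out

    return rhs


def ode_rhs(y: np.ndarray, t: TissueState, p: ModelParams) -> np.ndarray:
    """Convenience single-shot evaluation of the full right-hand side."""
    m = StateIndexMap.from_tissue(t)
    return make_rhs(m, p)(t.sim_time, y)


def spring_energy(t: TissueState, spring_k: float) -> float:
    """Total elastic energy ½kΣ(l − L0)² of all walls."""
    m = StateIndexMap.from_tissue(t)
    pos, rest = m.split(m.pack(t))
    length = np.linalg.norm(pos[m.wi2] - pos[m.wi1], axis=1)
    return 0.5 * spring_k * float(np.sum((length - rest) ** 2))
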