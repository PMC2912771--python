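"""Time-stepping driver: adaptive integration with division and removal events.

Between topology events the tissue evolves under a smooth ODE, integrated
with an adaptive fifth-order embedded Runge–Kutta pair.  After every
accepted step each cell whose area exceeds the threshold divides (in
ascending cell-id order), and cells whose centroid drifted past the
boundary radius are removed; any such topology change restarts the solver
with a freshly built index map.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import RK45

from .division import DivisionRule, make_plane, parse_rule
from .mechanics import ModelParams, StateIndexMap, make_rhs
from .tissue import Cell, DivisionError, TissueState, Vertex, Wall

logger = logging.getLogger(__name__)

__all__ = ["SimulationConfig", "Snapshot", "make_founder", "simulate", "run",
           "generate_initial_states", "run_oryzalin"]

#: cap on the solver step so division/removal checks are never starved
MAX_STEP = 2.0


@dataclass(frozen=True)
class Snapshot:
    """An immutable copy of the tissue at a requested time."""

    tissue: TissueState
    time: float


@dataclass
class SimulationConfig:
    """Everything needed to reproduce one run."""

    params: ModelParams = field(default_factory=ModelParams)
    rule: DivisionRule | str = "ShortestPathCOM"
    seed: int = 0
    t_end: float = 100.0
    snapshot_times: tuple[float, ...] = ()
    founder_vertices: int = 6
    founder_circumradius: float = 0.5
    init_tissue: TissueState | None = None

    def __post_init__(self):
        if isinstance(self.rule, str):
            self.rule = parse_rule(self.rule)
        for st in self.snapshot_times:
            if not 0.0 <= st <= self.t_end:
                raise ValueError("snapshot_times must lie within [0, t_end]")


def make_founder(n_vertices: int, circumradius: float = 0.5) -> TissueState:
    """Single regular-polygon founder cell centered at the origin.

    All wall resting lengths equal the realized side length, so the
    founder starts stress-free.
    """
    if not 3 <= n_vertices <= 15:
        raise ValueError("founder polygon must have 3 to 15 vertices")
    if circumradius <= 0:
        raise ValueError("circumradius must be positive")
    t = TissueState()
    side = 2.0 * circumradius * math.sin(math.pi / n_vertices)
    vids = []
    for k in range(n_vertices):
        th = 2.0 * math.pi * k / n_vertices
        v = Vertex(t.new_id(), circumradius * np.array([math.cos(th), math.sin(th)]))
        t.vertices[v.id] = v
        vids.append(v.id)
    wids = []
    for k in range(n_vertices):
        w = Wall(t.new_id(), vids[k], vids[(k + 1) % n_vertices], side)
        t.walls[w.id] = w
        wids.append(w.id)
    c = Cell(t.new_id(), wids)
    t.cells[c.id] = c
    return t


class _GeomCache:
    """Per-topology vertex-cycle index arrays for fast area/centroid checks."""

    def __init__(self, t: TissueState, m: StateIndexMap):
        vpos = {v: k for k, v in enumerate(m.vertex_ids)}
        self.cell_ids = sorted(t.cells)
        idx, nxt, offsets = [], [], []
        for cid in self.cell_ids:
            cyc = [vpos[v] for v in t.cell_vertex_cycle(cid)]
            offsets.append(len(idx))
            idx.extend(cyc)
            nxt.extend(cyc[1:] + cyc[:1])
        self.idx = np.array(idx, dtype=np.intp)
        self.nxt = np.array(nxt, dtype=np.intp)
        self.offsets = np.array(offsets, dtype=np.intp)

    def areas_centroids(self, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        xi, yi = pos[self.idx, 0], pos[self.idx, 1]
        xn, yn = pos[self.nxt, 0], pos[self.nxt, 1]
        cr = xi * yn - xn * yi
        areas = 0.5 * np.add.reduceat(cr, self.offsets)
        with np.errstate(divide="ignore", invalid="ignore"):
            cx = np.add.reduceat((xi + xn) * cr, self.offsets) / (6.0 * areas)
            cy = np.add.reduceat((yi + yn) * cr, self.offsets) / (6.0 * areas)
        return areas, np.stack([cx, cy], axis=1)


def _handle_events(t: TissueState, params: ModelParams, rule: DivisionRule,
                   rng: np.random.Generator) -> bool:
    """Apply divisions and boundary removal; return True on topology change."""
    changed = False
    if params.division_enabled:
        for cid in sorted(t.cells):
            if cid not in t.cells:
                continue
            if t.cell_area(cid) > params.area_threshold:
                try:
                    plane = make_plane(t, cid, rule, rng,
                                       signed_strain=params.signed_strain,
                                       strain_weight=params.strain_weight)
                    t.split_cell(cid, plane, d_threshold=params.d_threshold)
                    changed = True
                except DivisionError as exc:
                    logger.warning("division of cell %d aborted: %s", cid, exc)
        if t.remove_outside_cells(params.radius_threshold):
            changed = True
    return changed


def simulate(t: TissueState, params: ModelParams, rule: DivisionRule,
             rng: np.random.Generator, t_end: float | None = None,
             snapshot_times: tuple[float, ...] = (),
             stop_condition=None) -> list[Snapshot]:
    """Advance ``t`` in place; return snapshots at the requested times.

    ``stop_condition(t)`` is checked after every event pass and ends the
    run early; it is required when ``t_end`` is None.
    """
    if t_end is None and stop_condition is None:
        raise ValueError("need t_end or stop_condition")
    t_stop = math.inf if t_end is None else t.sim_time + t_end
    pending = sorted(st + t.sim_time for st in snapshot_times)
    snaps: list[Snapshot] = []

    def record_due():
        while pending and (t.sim_time >= pending[0]
                           or math.isclose(pending[0], t.sim_time)):
            t.rng_state = rng.bit_generator.state
            snaps.append(Snapshot(tissue=t.copy(), time=t.sim_time))
            pending.pop(0)

    record_due()
    if stop_condition is not None and stop_condition(t):
        return snaps

    while t.sim_time < t_stop and not math.isclose(t.sim_time, t_stop):
        m = StateIndexMap.from_tissue(t)
        cache = _GeomCache(t, m)
        y0 = m.pack(t)
        bound = pending[0] if pending else t_stop
        if math.isinf(bound):
            bound = t.sim_time + 1e6
        solver = RK45(make_rhs(m, params), t.sim_time, y0, t_bound=bound,
                      rtol=params.ode_rel_tol, atol=params.ode_abs_tol,
                      max_step=MAX_STEP)
        while solver.status == "running":
            msg = solver.step()
            if solver.status == "failed":
                raise RuntimeError(f"ODE solver failed at t={solver.t}: {msg}")
            pos, _ = m.split(solver.y)
            need_sync = False
            if params.division_enabled:
                areas, cents = cache.areas_centroids(pos)
                over = np.any(areas > params.area_threshold)
                out = np.any(np.linalg.norm(cents, axis=1) > params.radius_threshold)
                need_sync = bool(over or out)
            if need_sync:
                m.unpack(solver.y, t)
                t.sim_time = solver.t
                if _handle_events(t, params, rule, rng):
                    # topology (and hence cell count) changed
                    record_due()
                    if stop_condition is not None and stop_condition(t):
                        return snaps
                    break  # rebuild index map and solver
        else:
            # reached the time bound
            m.unpack(solver.y, t)
            t.sim_time = solver.t
            record_due()
    return snaps


def run(config: SimulationConfig) -> list[Snapshot]:
    """Run a complete simulation described by a :class:`SimulationConfig`."""
    rng = np.random.default_rng(config.seed)
    if config.init_tissue is not None:
        t = config.init_tissue.copy()
    else:
        t = make_founder(config.founder_vertices, config.founder_circumradius)
    snapshot_times = config.snapshot_times or (config.t_end,)
    return simulate(t, config.params, config.rule, rng,
                    t_end=config.t_end, snapshot_times=snapshot_times)


def generate_initial_states(seed: int, n_founders: int = 13,
                            snapshots_per_founder: int = 25,
                            params: ModelParams | None = None,
                            min_cells: int = 150,
                            snapshot_spacing: float = 50.0,
                            max_time: float = 1e5) -> list[TissueState]:
    """Library of steady-state tissues grown with ShortestPath⊗COM.

    Each founder (regular polygons of 3 up to ``2 + n_founders`` vertices)
    is grown until the tissue first holds ``min_cells`` cells, then
    ``snapshots_per_founder`` snapshots are captured at even time spacing.
    """
    if n_founders < 1 or snapshots_per_founder < 1:
        raise ValueError("counts must be >= 1")
    if n_founders > 13:
        raise ValueError("at most 13 founder polygons (3 to 15 vertices)")
    params = params or ModelParams()
    rule = parse_rule("ShortestPathCOM")
    rng = np.random.default_rng(seed)
    states: list[TissueState] = []
    for k in range(n_founders):
        t = make_founder(3 + k)
        simulate(t, params, rule, rng, t_end=max_time,
                 stop_condition=lambda s: len(s.cells) >= min_cells)
        if len(t.cells) < min_cells:
            raise RuntimeError(f"founder {3 + k}: steady state not reached "
                               f"within {max_time} time units")
        times = tuple(snapshot_spacing * (i + 1) for i in range(snapshots_per_founder))
        snaps = simulate(t, params, rule, rng,
                         t_end=times[-1], snapshot_times=times)
        states.extend(s.tissue for s in snaps)
        logger.info("founder %d-gon: %d snapshots, %d cells at end",
                    3 + k, len(snaps), len(t.cells))
    return states


def run_oryzalin(initial: TissueState, params: ModelParams | None = None,
                 t_end: float = 200.0,
                 snapshot_times: tuple[float, ...] = ()) -> list[Snapshot]:
    """Continue a grown tissue with cell division suppressed.

    Emulates the oryzalin microtubule-depolymerization experiment: growth
    continues, no new walls form, and boundary removal is likewise off so
    the tracked cell population is preserved.  Cell/wall/vertex counts are
    invariant over the run.
    """
    params = (params or ModelParams()).oryzalin()
    t = initial.copy()
    rng = np.random.default_rng(0)  # no stochastic choices occur without division
    snaps = simulate(t, params, parse_rule("ShortestPathCOM"), rng,
                     t_end=t_end, snapshot_times=snapshot_times or (t_end,))
    return snaps
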