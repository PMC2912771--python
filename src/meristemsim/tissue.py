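"""Vertex/wall/cell mesh data model and topological edit operations.

The tissue is the standard 2-D vertex-model representation of a plant
epidermis: point vertices joined by straight walls (springs with a resting
length), and cells given by closed cycles of walls.  Three-way wall
junctions are the rule; the division operation actively avoids creating
four-way junctions.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .geometry import polygon_centroid, signed_area

logger = logging.getLogger(__name__)

__all__ = ["Vertex", "Wall", "Cell", "TissueState", "DivisionError"]


class DivisionError(RuntimeError):
    """A cell division could not be carried out (cell is retried later)."""


@dataclass
class Vertex:
    id: int
    pos: np.ndarray  # shape (2,)


@dataclass
class Wall:
    """A straight wall segment between two vertices, acting as a spring.

    ``rest_length`` is the stress-free spring length; it grows under
    tension (see :mod:`meristemsim.mechanics`).
    """

    id: int
    v1: int
    v2: int
    rest_length: float

    def other(self, vid: int) -> int:
        return self.v2 if vid == self.v1 else self.v1


@dataclass
class Cell:
    """A cell: a closed cycle of walls.

    ``last_division_direction`` stores the axial direction of the wall
    created when this cell was born, which the Orthogonal division rule
    consults.
    """

    id: int
    walls: list[int]
    last_division_direction: np.ndarray | None = None


@dataclass
class TissueState:
    """Complete mutable simulation state.

    Invariants (see :meth:`check_integrity`): referential integrity, every
    wall borders one or two cells, no vertex joins more than three walls.
    """

    vertices: dict[int, Vertex] = field(default_factory=dict)
    walls: dict[int, Wall] = field(default_factory=dict)
    cells: dict[int, Cell] = field(default_factory=dict)
    sim_time: float = 0.0
    rng_state: dict | None = None
    _next_id: int = 0

    # -- id management -------------------------------------------------
    def new_id(self) -> int:
        self._next_id += 1
        return self._next_id - 1

    def copy(self) -> "TissueState":
        return copy.deepcopy(self)

    # -- derived topology ----------------------------------------------
    def wall_cells(self) -> dict[int, list[int]]:
        """Map wall id -> ids of incident cells (1 or 2)."""
        out: dict[int, list[int]] = {w: [] for w in self.walls}
        for c in self.cells.values():
            for w in c.walls:
                out[w].append(c.id)
        return out

    def vertex_walls(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {v: [] for v in self.vertices}
        for w in self.walls.values():
            out[w.v1].append(w.id)
            out[w.v2].append(w.id)
        return out

    def cell_vertex_cycle(self, cell_id: int) -> list[int]:
        """Ordered vertex ids around the cell, CCW, aligned with the wall cycle.

        Vertex ``k`` is shared by walls ``k-1`` and ``k`` of the (possibly
        re-oriented) wall cycle; the cycle is rotated so that wall ``k``
        connects vertex ``k`` to vertex ``k+1``.
        """
        cell = self.cells[cell_id]
        wids = cell.walls
        if len(wids) < 3:
            raise ValueError(f"cell {cell_id} has fewer than 3 walls")
        # orient walls head-to-tail
        w0, w1 = self.walls[wids[0]], self.walls[wids[1]]
        if w0.v2 in (w1.v1, w1.v2):
            start = w0.v1
        elif w0.v1 in (w1.v1, w1.v2):
            start = w0.v2
        else:
            raise ValueError(f"cell {cell_id}: walls {wids[0]} and {wids[1]} not adjacent")
        cycle = [start]
        cur = start
        for wid in wids[:-1]:
            cur = self.walls[wid].other(cur)
            cycle.append(cur)
        last = self.walls[wids[-1]]
        if {last.v1, last.v2} != {cycle[-1], cycle[0]}:
            raise ValueError(f"cell {cell_id}: wall cycle does not close")
        # enforce CCW on the geometric polygon
        pts = np.array([self.vertices[v].pos for v in cycle])
        if signed_area(pts) < 0:
            cycle.reverse()
            cycle = [cycle[-1]] + cycle[:-1]
            cell.walls = list(reversed(wids))
        return cycle

    def cell_polygon(self, cell_id: int) -> np.ndarray:
        """CCW polygon of the cell's vertex positions."""
        cycle = self.cell_vertex_cycle(cell_id)
        return np.array([self.vertices[v].pos for v in cycle])

    def cell_area(self, cell_id: int) -> float:
        return signed_area(self.cell_polygon(cell_id))

    def cell_centroid(self, cell_id: int) -> np.ndarray:
        return polygon_centroid(self.cell_polygon(cell_id))

    def neighbor_count(self, cell_id: int) -> int:
        """Number of walls this cell shares with other cells.

        For interior cells this is the conventional neighbor number used
        in epithelial topology statistics.
        """
        wc = self.wall_cells()
        return sum(1 for w in self.cells[cell_id].walls if len(wc[w]) == 2)

    def boundary_cells(self) -> set[int]:
        """Cells owning at least one wall with a single incident cell."""
        wc = self.wall_cells()
        out = set()
        for c in self.cells.values():
            if any(len(wc[w]) == 1 for w in c.walls):
                out.add(c.id)
        return out

    def interior_cells(self) -> list[int]:
        bdry = self.boundary_cells()
        return [c for c in self.cells if c not in bdry]

    # -- integrity -------------------------------------------------------
    def check_integrity(self) -> None:
        """Raise ``AssertionError`` on any violated structural invariant."""
        for w in self.walls.values():
            assert w.v1 in self.vertices and w.v2 in self.vertices, f"wall {w.id} dangling"
            assert w.v1 != w.v2, f"wall {w.id} is a loop"
            assert w.rest_length > 0, f"wall {w.id} rest_length <= 0"
        wc = self.wall_cells()
        for wid, cids in wc.items():
            assert 1 <= len(cids) <= 2, f"wall {wid} borders {len(cids)} cells"
        for vid, wids in self.vertex_walls().items():
            assert 1 <= len(wids) <= 3, f"vertex {vid} joins {len(wids)} walls"
        for c in self.cells.values():
            cyc = self.cell_vertex_cycle(c.id)
            assert len(cyc) == len(c.walls)
            assert signed_area(np.array([self.vertices[v].pos for v in cyc])) > 0

    # -- edits -----------------------------------------------------------
    def split_cell(self, cell_id: int, plane, d_threshold: float = 0.0) -> tuple[int, int]:
        """Divide a cell along a straight plane.

        ``plane`` carries ``center`` (a point strictly inside the cell) and
        ``direction`` (an axial unit vector).  Two new vertices are placed
        where the chord through the center meets the cell outline; the two
        cut walls are each split into two walls whose resting lengths are
        the proportional shares of the original, and a new wall joining the
        new vertices gets a resting length equal to its realized length.
        A new vertex closer than ``d_threshold`` to an existing junction is
        slid along its wall to exactly that distance (four-way-junction
        avoidance).  Returns the two daughter cell ids.

        Raises :class:`DivisionError` when no valid chord exists or the
        junction-avoidance move cannot be made.
        """
        cell = self.cells[cell_id]
        cycle = self.cell_vertex_cycle(cell_id)
        poly = np.array([self.vertices[v].pos for v in cycle])
        n = len(cycle)
        c = np.asarray(plane.center, dtype=float)
        if not geometry.point_in_polygon(poly, c):
            raise DivisionError(f"division center outside cell {cell_id}")
        try:
            q1, q2, e1, e2, s1, s2, _ = geometry.chord_through_point(
                poly, c, plane.direction, d_min=1e-9
            )
        except ValueError as exc:
            raise DivisionError(str(exc)) from exc
        if e1 == e2:
            raise DivisionError(f"chord cuts a single wall of cell {cell_id}")

        # four-vertex avoidance: slide endpoints to >= d_threshold from the
        # wall's endpoints; abort when the wall is too short to allow it
        edge_vecs = np.roll(poly, -1, axis=0) - poly
        new_pts = []
        for e_i, s_i, q_i in ((e1, s1, q1), (e2, s2, q2)):
            elen = float(np.linalg.norm(edge_vecs[e_i]))
            if d_threshold > 0.0:
                if elen < 2.0 * d_threshold:
                    raise DivisionError(
                        f"wall too short ({elen:.3g}) for junction avoidance in cell {cell_id}"
                    )
                s_min = d_threshold / elen
                s_i = min(max(s_i, s_min), 1.0 - s_min)
            new_pts.append((e_i, s_i, poly[e_i] + s_i * edge_vecs[e_i]))
        (e1, s1, q1), (e2, s2, q2) = new_pts

        wall_cells = self.wall_cells()
        daughters = []
        # create new vertices
        nv1 = Vertex(self.new_id(), np.asarray(q1, dtype=float))
        nv2 = Vertex(self.new_id(), np.asarray(q2, dtype=float))
        self.vertices[nv1.id] = nv1
        self.vertices[nv2.id] = nv2

        # split the two cut walls; wall at cycle position k joins cycle[k]
        # and cycle[(k+1) % n], and s is measured from cycle[k]
        replacements: dict[int, tuple[int, int]] = {}
        halves_at: dict[int, tuple[Wall, Wall]] = {}
        for e_i, s_i, nv in ((e1, s1, nv1), (e2, s2, nv2)):
            va, vb = cycle[e_i], cycle[(e_i + 1) % n]
            old = self._wall_between(cell.walls, va, vb)
            wa = Wall(self.new_id(), va, nv.id, old.rest_length * s_i)
            wb = Wall(self.new_id(), nv.id, vb, old.rest_length * (1.0 - s_i))
            self.walls[wa.id] = wa
            self.walls[wb.id] = wb
            replacements[old.id] = (wa.id, wb.id)
            halves_at[e_i] = (wa, wb)
            # update the neighbor sharing this wall
            for nc_id in wall_cells[old.id]:
                if nc_id == cell_id:
                    continue
                self._replace_wall_in_cycle(self.cells[nc_id], old.id, [wa.id, wb.id])
            del self.walls[old.id]

        new_wall = Wall(
            self.new_id(), nv1.id, nv2.id, float(np.linalg.norm(q2 - q1))
        )
        self.walls[new_wall.id] = new_wall
        axial = (q2 - q1) / np.linalg.norm(q2 - q1)

        # daughter wall cycles: walk the mother cycle between the cut edges
        def arc(from_e: int, to_e: int) -> list[int]:
            """Wall ids (post-split) from edge ``from_e`` second half through
            edge ``to_e`` first half, inclusive."""
            out = [halves_at[from_e][1].id]
            k = (from_e + 1) % n
            while k != to_e:
                va, vb = cycle[k], cycle[(k + 1) % n]
                out.append(self._wall_between(cell.walls, va, vb).id)
                k = (k + 1) % n
            out.append(halves_at[to_e][0].id)
            return out

        cyc1 = arc(e1, e2) + [new_wall.id]
        cyc2 = arc(e2, e1) + [new_wall.id]
        for cyc in (cyc1, cyc2):
            d = Cell(self.new_id(), cyc, last_division_direction=axial.copy())
            self.cells[d.id] = d
            daughters.append(d.id)
        del self.cells[cell_id]
        logger.info(
            "division: cell %d -> (%d, %d), center=(%.4f, %.4f), dir=%.4f rad",
            cell_id, daughters[0], daughters[1], c[0], c[1],
            math.atan2(axial[1], axial[0]) % math.pi,
        )
        return daughters[0], daughters[1]

    def _wall_between(self, wids: list[int], va: int, vb: int) -> Wall:
        for wid in wids:
            w = self.walls.get(wid)
            if w is not None and {w.v1, w.v2} == {va, vb}:
                return w
        raise ValueError(f"no wall between vertices {va} and {vb}")

    def _replace_wall_in_cycle(self, cell: Cell, old_wid: int, new_wids: list[int]) -> None:
        """Substitute a split wall by its two halves, head-to-tail ordered."""
        k = cell.walls.index(old_wid)
        prev_w = self.walls.get(cell.walls[(k - 1) % len(cell.walls)])
        next_w = self.walls.get(cell.walls[(k + 1) % len(cell.walls)])
        order = list(new_wids)
        if prev_w is not None:
            first = self.walls[order[0]]
            if not ({first.v1, first.v2} & {prev_w.v1, prev_w.v2}):
                order.reverse()
        elif next_w is not None:
            last = self.walls[order[-1]]
            if not ({last.v1, last.v2} & {next_w.v1, next_w.v2}):
                order.reverse()
        cell.walls = cell.walls[:k] + order + cell.walls[k + 1:]

    def remove_outside_cells(self, radius: float) -> int:
        """Delete every cell whose centroid lies farther than ``radius``
        from the origin, with any walls and vertices no longer used."""
        doomed = [
            cid for cid in self.cells
            if float(np.linalg.norm(self.cell_centroid(cid))) > radius
        ]
        for cid in doomed:
            del self.cells[cid]
            logger.info("removal: cell %d beyond radius %.3g", cid, radius)
        if doomed:
            used_walls = {w for c in self.cells.values() for w in c.walls}
            self.walls = {w: self.walls[w] for w in used_walls}
            used_verts = {v for w in self.walls.values() for v in (w.v1, w.v2)}
            self.vertices = {v: self.vertices[v] for v in used_verts}
        return len(doomed)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "sim_time": self.sim_time,
            "next_id": self._next_id,
            "rng_state": self.rng_state,
            "vertices": [
                [v.id, float(v.pos[0]), float(v.pos[1])] for v in self.vertices.values()
            ],
            "walls": [
                [w.id, w.v1, w.v2, w.rest_length] for w in self.walls.values()
            ],
            "cells": [
                {
                    "id": c.id,
                    "walls": list(c.walls),
                    "last_division_direction": (
                        None if c.last_division_direction is None
                        else [float(c.last_division_direction[0]),
                              float(c.last_division_direction[1])]
                    ),
                }
                for c in self.cells.values()
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TissueState":
        t = cls(sim_time=float(d["sim_time"]), rng_state=d.get("rng_state"))
        t._next_id = int(d["next_id"])
        for vid, x, y in d["vertices"]:
            t.vertices[int(vid)] = Vertex(int(vid), np.array([x, y], dtype=float))
        for wid, v1, v2, rl in d["walls"]:
            t.walls[int(wid)] = Wall(int(wid), int(v1), int(v2), float(rl))
        for c in d["cells"]:
            ldd = c.get("last_division_direction")
            t.cells[int(c["id"])] = Cell(
                int(c["id"]),
                [int(w) for w in c["walls"]],
                None if ldd is None else np.array(ldd, dtype=float),
            )
        return t
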