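"""Shared fixtures and tissue builders for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from meristemsim.tissue import Cell, TissueState, Vertex, Wall


def star_polygon(rng: np.random.Generator, n: int = 8,
                 r_min: float = 0.4, r_max: float = 1.4) -> np.ndarray:
    """Random star-shaped (hence simple) polygon around the origin."""
    # one vertex per angular sector: distinct sorted angles spanning the
    # full circle, so the polygon is star-shaped about the origin
    thetas = 2.0 * math.pi * (np.arange(n) + rng.uniform(0.05, 0.95, n)) / n
    r = rng.uniform(r_min, r_max, n)
    return np.stack([r * np.cos(thetas), r * np.sin(thetas)], axis=1)


def build_tissue(points: dict[int, tuple], walls: list[tuple[int, int, int, float]],
                 cells: dict[int, list[int]]) -> TissueState:
    """Assemble a TissueState from literal vertex/wall/cell specs."""
    t = TissueState()
    for vid, p in points.items():
        t.vertices[vid] = Vertex(vid, np.asarray(p, dtype=float))
    for wid, v1, v2, rl in walls:
        t.walls[wid] = Wall(wid, v1, v2, float(rl))
    for cid, wids in cells.items():
        t.cells[cid] = Cell(cid, list(wids))
    t._next_id = 1 + max([*points, *(w[0] for w in walls), *cells])
    return t


def square_cell(rest: float = 1.0) -> TissueState:
    """Single unit-square cell."""
    return build_tissue(
        points={0: (0, 0), 1: (1, 0), 2: (1, 1), 3: (0, 1)},
        walls=[(4, 0, 1, rest), (5, 1, 2, rest), (6, 2, 3, rest), (7, 3, 0, rest)],
        cells={8: [4, 5, 6, 7]},
    )


def hex_rosette() -> TissueState:
    """Seven hexagonal cells: one center, six around it.

    Built on a honeycomb lattice with vertex/wall deduplication; the
    center cell is interior (all six walls shared), the ring is boundary.
    """
    t = TissueState()
    vindex: dict[tuple[int, int], int] = {}
    windex: dict[frozenset, int] = {}
    side = 1.0

    def vertex_at(x: float, y: float) -> int:
        key = (round(x * 1e6), round(y * 1e6))
        if key not in vindex:
            v = Vertex(t.new_id(), np.array([x, y]))
            t.vertices[v.id] = v
            vindex[key] = v.id
        return vindex[key]

    def wall_between(a: int, b: int) -> int:
        key = frozenset((a, b))
        if key not in windex:
            la = t.vertices[a].pos
            lb = t.vertices[b].pos
            w = Wall(t.new_id(), a, b, float(np.linalg.norm(lb - la)))
            t.walls[w.id] = w
            windex[key] = w.id
        return windex[key]

    centers = [(0.0, 0.0)]
    for k in range(6):
        th = math.pi / 6 + k * math.pi / 3
        centers.append((math.sqrt(3) * side * math.cos(th),
                        math.sqrt(3) * side * math.sin(th)))
    for cx, cy in centers:
        vids = []
        for k in range(6):
            th = k * math.pi / 3
            vids.append(vertex_at(cx + side * math.cos(th), cy + side * math.sin(th)))
        wids = [wall_between(vids[k], vids[(k + 1) % 6]) for k in range(6)]
        c = Cell(t.new_id(), wids)
        t.cells[c.id] = c
    return t


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)


@pytest.fixture
def square() -> TissueState:
    return square_cell()


@pytest.fixture
def rosette() -> TissueState:
    return hex_rosette()
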