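"""Pure 2-D polygon computations.

Polygons are represented as ``(n, 2)`` float arrays of vertex coordinates
in counterclockwise (CCW) order.  All routines here are free functions on
such arrays; :func:`as_polygon` validates and canonicalizes input.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "as_polygon",
    "polygon_area",
    "signed_area",
    "polygon_centroid",
    "chord_through_point",
    "chord_endpoints_grid",
    "random_point_in_polygon",
    "internal_vertex_angles",
    "point_in_polygon",
    "triangulate",
]

#: below this, a chord endpoint is considered to hit a polygon vertex
VERTEX_HIT_TOL = 1e-9
#: rotation applied to the chord direction when it hits a vertex
PERTURB_ANGLE = 1e-7
MAX_PERTURB_RETRIES = 64


def as_polygon(points, validate: bool = True) -> np.ndarray:
    """Return a CCW-oriented ``(n, 2)`` float array.

    CW input is reversed.  With ``validate=True`` degenerate input
    (fewer than 3 vertices, non-finite coordinates, zero area) raises
    ``ValueError``.
    """
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2:
        raise ValueError(f"polygon must be an (n, 2) array, got shape {p.shape}")
    if validate:
        if p.shape[0] < 3:
            raise ValueError("polygon needs at least 3 vertices")
        if not np.all(np.isfinite(p)):
            raise ValueError("polygon has non-finite coordinates")
    a = signed_area(p)
    if validate and a == 0.0:
        raise ValueError("degenerate polygon (zero area)")
    if a < 0:
        p = p[::-1].copy()
    return p


def signed_area(p: np.ndarray) -> float:
    """Shoelace signed area; positive for CCW orientation."""
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_area(p) -> float:
    """Area of a simple polygon (shoelace formula)."""
    p = as_polygon(p)
    return signed_area(p)


def polygon_centroid(p) -> np.ndarray:
    """Area-weighted centroid of a uniform lamina (not the vertex mean)."""
    p = as_polygon(p)
    x, y = p[:, 0], p[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * float(np.sum(cross))
    if a == 0.0:
        raise ValueError("zero-area polygon has no centroid")
    cx = float(np.sum((x + xn) * cross)) / (6.0 * a)
    cy = float(np.sum((y + yn) * cross)) / (6.0 * a)
    return np.array([cx, cy])


def point_in_polygon(p: np.ndarray, q) -> bool:
    """Even-odd ray-casting containment test (boundary points undefined)."""
    x, y = float(q[0]), float(q[1])
    px, py = p[:, 0], p[:, 1]
    pxn, pyn = np.roll(px, -1), np.roll(py, -1)
    straddle = (py > y) != (pyn > y)
    with np.errstate(divide="ignore", invalid="ignore"):
        xint = px + (y - py) / (pyn - py) * (pxn - px)
    hits = straddle & (x < xint)
    return bool(np.count_nonzero(hits) % 2)


def _line_edge_params(p: np.ndarray, c: np.ndarray, u: np.ndarray):
    """Intersection parameters of the line ``c + t*u`` with every edge.

    Returns ``(t, s, valid)`` where edge ``j`` runs from vertex ``j`` to
    ``j+1``, ``s`` is the fractional position along the edge and ``valid``
    flags non-parallel edges with ``s`` in ``[0, 1)``.  The half-open
    interval makes every polygon vertex belong to exactly one edge.
    """
    a = p
    e = np.roll(p, -1, axis=0) - p
    denom = u[0] * e[:, 1] - u[1] * e[:, 0]  # cross(u, e)
    w = a - c
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (w[:, 0] * e[:, 1] - w[:, 1] * e[:, 0]) / denom
        s = (w[:, 0] * u[1] - w[:, 1] * u[0]) / denom
    valid = (np.abs(denom) > 1e-300) & (s >= 0.0) & (s < 1.0)
    return t, s, valid


def chord_through_point(p, c, direction, d_min: float | None = None):
    """Chord of the polygon through interior point ``c`` along ``direction``.

    Returns ``(q1, q2, e1, e2, s1, s2, dir_used)`` where ``q1``/``q2`` are
    the endpoints of the maximal segment through ``c`` that stays inside the
    polygon, ``e1``/``e2`` the indices of the edges they lie on and
    ``s1``/``s2`` the fractional positions along those edges.  ``q1`` lies on
    the negative side of ``c`` along the direction.

    If an endpoint falls within ``d_min`` (default :data:`VERTEX_HIT_TOL`)
    of a polygon vertex the direction is rotated by a tiny angle and the
    search retried, since the downstream division construction requires the
    chord to cut two wall interiors.
    """
    p = as_polygon(p, validate=False)
    c = np.asarray(c, dtype=float)
    u = np.asarray(direction, dtype=float)
    nu = math.hypot(u[0], u[1])
    if nu == 0.0:
        raise ValueError("direction must be nonzero")
    u = u / nu
    if d_min is None:
        d_min = VERTEX_HIT_TOL
    edge_len = np.linalg.norm(np.roll(p, -1, axis=0) - p, axis=1)

    theta0 = math.atan2(u[1], u[0])
    for k in range(MAX_PERTURB_RETRIES):
        th = theta0 + k * PERTURB_ANGLE
        uu = np.array([math.cos(th), math.sin(th)])
        t, s, valid = _line_edge_params(p, c, uu)
        tv = t[valid]
        if tv.size < 2 or not (np.any(tv > 0) and np.any(tv < 0)):
            continue
        t_pos = np.min(tv[tv > 0])
        t_neg = np.max(tv[tv < 0])
        e2 = int(np.flatnonzero(valid & (t == t_pos))[0])
        e1 = int(np.flatnonzero(valid & (t == t_neg))[0])
        s1, s2 = float(s[e1]), float(s[e2])
        # reject endpoints too close to a polygon vertex
        ok = True
        for e_i, s_i in ((e1, s1), (e2, s2)):
            d_lo = s_i * edge_len[e_i]
            d_hi = (1.0 - s_i) * edge_len[e_i]
            if min(d_lo, d_hi) < d_min:
                ok = False
                break
        if not ok:
            continue
        q1 = c + t_neg * uu
        q2 = c + t_pos * uu
        return q1, q2, e1, e2, s1, s2, uu
    raise ValueError("could not find a chord avoiding polygon vertices")


def chord_endpoints_grid(p: np.ndarray, c: np.ndarray, thetas: np.ndarray) -> np.ndarray:
    """Chord lengths through ``c`` for many axial directions at once.

    Vectorized over ``thetas`` (angles in [0, π)); used by the
    shortest-path division-direction search.  Directions whose chord is
    degenerate get ``inf``.
    """
    u = np.stack([np.cos(thetas), np.sin(thetas)], axis=1)  # (m, 2)
    a = p
    e = np.roll(p, -1, axis=0) - p  # (n, 2)
    w = a - c  # (n, 2)
    denom = u[:, 0:1] * e[:, 1] - u[:, 1:2] * e[:, 0]  # (m, n)
    num_t = w[:, 0] * e[:, 1] - w[:, 1] * e[:, 0]  # (n,)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num_t / denom  # (m, n)
        s = (w[:, 0] * u[:, 1:2] - w[:, 1] * u[:, 0:1]) / denom
    valid = (np.abs(denom) > 1e-300) & (s >= 0.0) & (s < 1.0)
    t_pos = np.where(valid & (t > 0), t, np.inf).min(axis=1)
    t_neg = np.where(valid & (t < 0), t, -np.inf).max(axis=1)
    lengths = t_pos - t_neg
    lengths[~np.isfinite(lengths)] = np.inf
    return lengths


def triangulate(p: np.ndarray) -> list[tuple[int, int, int]]:
    """Ear-clipping triangulation; returns vertex-index triples.

    Works for simple polygons, convex or not.
    """
    p = as_polygon(p)
    idx = list(range(len(p)))
    tris: list[tuple[int, int, int]] = []
    guard = 0
    while len(idx) > 3:
        guard += 1
        if guard > 10000:
            raise ValueError("triangulation failed (polygon may be non-simple)")
        n = len(idx)
        clipped = False
        for k in range(n):
            i0, i1, i2 = idx[(k - 1) % n], idx[k], idx[(k + 1) % n]
            a, b, cpt = p[i0], p[i1], p[i2]
            cross = (b[0] - a[0]) * (cpt[1] - a[1]) - (b[1] - a[1]) * (cpt[0] - a[0])
            if cross <= 0:
                continue  # reflex or degenerate ear
            tri = np.array([a, b, cpt])
            # no remaining vertex may lie inside the candidate ear
            others = [j for j in idx if j not in (i0, i1, i2)]
            if others and any(_in_triangle(tri, p[j]) for j in others):
                continue
            tris.append((i0, i1, i2))
            idx.pop(k)
            clipped = True
            break
        if not clipped:
            raise ValueError("no ear found (polygon may be non-simple)")
    tris.append((idx[0], idx[1], idx[2]))
    return tris


def _in_triangle(tri: np.ndarray, q: np.ndarray) -> bool:
    a, b, c = tri
    d1 = (q[0] - b[0]) * (a[1] - b[1]) - (a[0] - b[0]) * (q[1] - b[1])
    d2 = (q[0] - c[0]) * (b[1] - c[1]) - (b[0] - c[0]) * (q[1] - c[1])
    d3 = (q[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (q[1] - a[1])
    has_neg = (d1 < 0) or (d2 < 0) or (d3 < 0)
    has_pos = (d1 > 0) or (d2 > 0) or (d3 > 0)
    return not (has_neg and has_pos)


def random_point_in_polygon(p, rng: np.random.Generator) -> np.ndarray:
    """Uniform sample over the polygon interior.

    Triangulates once, picks a triangle with probability proportional to
    its area, then samples uniformly inside it.
    """
    p = as_polygon(p)
    tris = triangulate(p)
    verts = np.array([[p[i], p[j], p[k]] for i, j, k in tris])  # (T, 3, 2)
    ab = verts[:, 1] - verts[:, 0]
    ac = verts[:, 2] - verts[:, 0]
    areas = 0.5 * np.abs(ab[:, 0] * ac[:, 1] - ab[:, 1] * ac[:, 0])
    ti = rng.choice(len(tris), p=areas / areas.sum())
    r1, r2 = rng.random(2)
    if r1 + r2 > 1.0:
        r1, r2 = 1.0 - r1, 1.0 - r2
    return verts[ti, 0] + r1 * ab[ti] + r2 * ac[ti]


def internal_vertex_angles(p) -> np.ndarray:
    """Interior angle at each vertex, in radians, each in (0, 2π).

    For a simple polygon the angles sum to ``(n - 2)π``; reflex vertices of
    non-convex polygons contribute angles above π.
    """
    p = as_polygon(p)
    prev = np.roll(p, 1, axis=0)
    nxt = np.roll(p, -1, axis=0)
    v1 = prev - p
    v2 = nxt - p
    ang = np.arctan2(
        v2[:, 0] * v1[:, 1] - v2[:, 1] * v1[:, 0],
        v2[:, 0] * v1[:, 0] + v2[:, 1] * v1[:, 1],
    )
    # CCW polygon: interior angle is the CCW angle from the outgoing edge
    # (towards next) to the incoming edge (towards prev)
    ang = np.mod(ang, 2.0 * np.pi)
    if np.any(ang == 0.0):
        raise ValueError("degenerate (collinear spike) vertex")
    return ang
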