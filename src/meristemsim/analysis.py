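"""Tissue-level topology and geometry statistics.

All statistics are computed over interior cells only — cells touching the
tissue boundary are excluded, since the boundary condition distorts both
their shape and their neighbor count.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import geometry
from .tissue import TissueState

__all__ = ["SnapshotStats", "ReferenceDistribution", "CUCUMBER_REFERENCE",
           "compute_stats", "neighbor_distribution", "distribution_moments",
           "deviation", "shape_measure", "angle_histogram",
           "ideal_angle_distribution", "ideal_angle_histogram",
           "total_variation", "lewis_law", "aggregate"]

#: isoperimetric upper bound of the shape measure (circular cells)
SHAPE_MAX = 1.0 / (4.0 * math.pi)

#: default angle-histogram binning: 36 bins over (0°, 180°]
ANGLE_BINS = np.linspace(0.0, math.pi, 37)


@dataclass
class SnapshotStats:
    """Per-snapshot interior-cell statistics."""

    neighbor_counts: np.ndarray       # int, one per interior cell
    areas: np.ndarray                 # one per interior cell
    shape_measures: np.ndarray        # one per interior cell
    angles: np.ndarray                # radians, one per interior vertex
    normalized_areas: np.ndarray      # areas / mean area over ALL cells
    n_cells_total: int = 0
    n_cells_interior: int = 0
    time: float = 0.0


@dataclass
class ReferenceDistribution:
    """Neighbor-number fractions an observed tissue is compared against."""

    fractions: dict[int, float]

    def __post_init__(self):
        total = sum(self.fractions.values())
        if any(f < 0 for f in self.fractions.values()):
            raise ValueError("fractions must be non-negative")
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValueError(f"fractions must sum to 1, got {total}")

    @classmethod
    def from_tsv(cls, path) -> "ReferenceDistribution":
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=["n", "fraction"])
        return cls({int(r.n): float(r.fraction) for r in df.itertuples()})


#: Classic cucumber-epidermis neighbor fractions (F.T. Lewis, 1920s):
#: 47% hexagons, more pentagons (25%) than heptagons (22%), range 4–8.
#: Shipped as a synthetic stand-in reference — supply your own measured
#: distribution for any quantitative comparison against experiments.
CUCUMBER_REFERENCE = ReferenceDistribution(
    {4: 0.03, 5: 0.25, 6: 0.47, 7: 0.22, 8: 0.03}
)


def compute_stats(t: TissueState) -> SnapshotStats:
    """Gather neighbor counts, areas, shapes and vertex angles of a tissue."""
    interior = sorted(t.interior_cells())
    all_areas = {cid: t.cell_area(cid) for cid in t.cells}
    mean_all = float(np.mean(list(all_areas.values()))) if all_areas else 1.0
    counts, areas, shapes, angles = [], [], [], []
    for cid in interior:
        poly = t.cell_polygon(cid)
        counts.append(t.neighbor_count(cid))
        areas.append(all_areas[cid])
        shapes.append(shape_measure(poly))
        angles.extend(geometry.internal_vertex_angles(poly))
    areas = np.asarray(areas, dtype=float)
    return SnapshotStats(
        neighbor_counts=np.asarray(counts, dtype=int),
        areas=areas,
        shape_measures=np.asarray(shapes, dtype=float),
        angles=np.asarray(angles, dtype=float),
        normalized_areas=areas / mean_all,
        n_cells_total=len(t.cells),
        n_cells_interior=len(interior),
        time=t.sim_time,
    )


def neighbor_distribution(counts) -> dict[int, float]:
    """Normalized histogram of neighbor numbers."""
    counts = np.asarray(counts, dtype=int)
    if counts.size == 0:
        raise ValueError("no interior cells to build a distribution from")
    c = Counter(counts.tolist())
    total = counts.size
    return {n: c[n] / total for n in sorted(c)}


def distribution_moments(counts) -> tuple[float, float]:
    """Population standard deviation and skewness of a neighbor-count sample.

    A constant sample has zero spread; its skewness is undefined and is
    reported as 0.0.
    """
    x = np.asarray(counts, dtype=float)
    mu = x.mean()
    std = float(np.sqrt(np.mean((x - mu) ** 2)))
    if std == 0.0:
        return 0.0, 0.0
    skew = float(np.mean((x - mu) ** 3) / std**3)
    return std, skew


def deviation(f: dict[int, float], ref: ReferenceDistribution,
              metric: str = "sq") -> float:
    """Mismatch between an observed and a reference neighbor distribution.

    Metrics: ``sq`` (default) sum of squared fraction differences, ``l1``
    sum of absolute differences, ``chi2`` squared differences scaled by the
    reference fraction (observed-only categories use the observed fraction
    as the scale).  Lower is better; 0 means identical distributions.
    """
    ns = set(f) | set(ref.fractions)
    d = 0.0
    for n in ns:
        fo = f.get(n, 0.0)
        fe = ref.fractions.get(n, 0.0)
        if metric == "sq":
            d += (fo - fe) ** 2
        elif metric == "l1":
            d += abs(fo - fe)
        elif metric == "chi2":
            scale = fe if fe > 0 else fo
            d += (fo - fe) ** 2 / scale
        else:
            raise ValueError(f"unknown deviation metric {metric!r}")
    return d


def shape_measure(poly) -> float:
    """Cell area divided by total wall length squared.

    Ranges from 0 (flat cells) to 1/(4π) ≈ 0.0796 (circular cells);
    a regular hexagon scores √3/24 ≈ 0.072.
    """
    p = geometry.as_polygon(poly)
    area = geometry.signed_area(p)
    perim = float(np.sum(np.linalg.norm(np.roll(p, -1, axis=0) - p, axis=1)))
    if perim == 0.0:
        return 0.0
    return area / perim**2


def angle_histogram(angles, bins=ANGLE_BINS) -> np.ndarray:
    """Density-normalized histogram of internal vertex angles (fractions)."""
    h, _ = np.histogram(np.asarray(angles, dtype=float), bins=bins)
    total = h.sum()
    return h / total if total else h.astype(float)


def ideal_angle_distribution(f: dict[int, float]) -> dict[float, float]:
    """Vertex-angle distribution if every cell were a regular polygon.

    A cell with ``n`` neighbors contributes ``n`` vertices at angle
    ``(n-2)π/n``, so cell fractions are re-weighted by vertex count.
    """
    weights = {n: n * fn for n, fn in f.items() if fn > 0}
    total = sum(weights.values())
    return {(n - 2) * math.pi / n: w / total for n, w in sorted(weights.items())}


def ideal_angle_histogram(f: dict[int, float], bins=ANGLE_BINS) -> np.ndarray:
    """The ideal distribution binned like :func:`angle_histogram`."""
    out = np.zeros(len(bins) - 1)
    for ang, w in ideal_angle_distribution(f).items():
        k = min(np.searchsorted(bins, ang, side="left") - 1, len(out) - 1)
        out[max(k, 0)] += w
    return out


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    """Total-variation distance between two binned distributions."""
    return 0.5 * float(np.abs(np.asarray(p) - np.asarray(q)).sum())


def lewis_law(stats: SnapshotStats) -> pd.DataFrame:
    """Mean normalized cell area per neighbor number, with a linear fit.

    Returns a frame with one row per observed ``n`` (columns ``n``,
    ``mean_area``, ``std_area``, ``count``) and attrs ``slope`` /
    ``intercept`` from a cell-count-weighted least-squares line, plus
    ``ref_slope`` / ``ref_intercept`` for the classical linear relation
    A_n = (n - 2)/4 between neighbor number and mean area.
    """
    n = stats.neighbor_counts
    a = stats.normalized_areas
    rows = []
    for nn in sorted(set(n.tolist())):
        sel = a[n == nn]
        rows.append({"n": nn, "mean_area": float(sel.mean()),
                     "std_area": float(sel.std(ddof=0)), "count": int(sel.size)})
    df = pd.DataFrame(rows)
    if len(df) >= 2:
        w = df["count"].to_numpy(dtype=float)
        slope, intercept = np.polyfit(df["n"], df["mean_area"], 1, w=np.sqrt(w))
    else:
        slope, intercept = math.nan, math.nan
    df.attrs.update(slope=float(slope), intercept=float(intercept),
                    ref_slope=0.25, ref_intercept=-0.5)
    return df


def aggregate(batch: list[SnapshotStats],
              ref: ReferenceDistribution | None = None,
              deviation_metric: str = "sq") -> dict[str, float]:
    """Across-snapshot summary of a batch of runs for one division rule.

    Per snapshot the neighbor-count std/skewness, mean shape measure and
    deviation from the reference are computed; the summary reports their
    across-snapshot means with sample standard deviations as errors.
    """
    if len(batch) < 1:
        raise ValueError("need at least one snapshot")
    ref = ref or CUCUMBER_REFERENCE
    per = {"std": [], "skew": [], "shape": [], "deviation": [],
           "n_interior": [], "n_total": []}
    for s in batch:
        if s.n_cells_interior == 0:
            # all cells touch the boundary (tiny tissue): no statistics
            per["std"].append(math.nan)
            per["skew"].append(math.nan)
            per["shape"].append(math.nan)
            per["deviation"].append(math.nan)
        else:
            std, skew = distribution_moments(s.neighbor_counts)
            per["std"].append(std)
            per["skew"].append(skew)
            per["shape"].append(float(s.shape_measures.mean()))
            per["deviation"].append(
                deviation(neighbor_distribution(s.neighbor_counts), ref,
                          metric=deviation_metric))
        per["n_interior"].append(s.n_cells_interior)
        per["n_total"].append(s.n_cells_total)
    out: dict[str, float] = {"n_snapshots": len(batch)}
    with np.errstate(invalid="ignore"):
        for key, vals in per.items():
            arr = np.asarray(vals, dtype=float)
            arr = arr[~np.isnan(arr)]
            out[f"{key}_mean"] = float(arr.mean()) if arr.size else math.nan
            out[f"{key}_err"] = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return out
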