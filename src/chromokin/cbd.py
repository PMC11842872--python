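"""Center-border-distance (CBD) analysis of nuclear track positions.

The CBD of a point inside a nucleus is the normalized radial coordinate
along the ray from the nuclear centroid through the point: 0 at the
centroid, 1 where the ray crosses the nuclear border.  Nuclear outlines
are drawn at keyframes (first/middle/last frame of a movie) and linearly
interpolated vertex-wise for every frame after resampling each polygon to
a common vertex count by arc length and cyclically aligning vertices.

CBD values are pooled into a histogram with five equal-width bins and
normalized by the ring area of each bin (proportional to (i+1)² - i² for a
unit disk) and by the largest bin value, with counting errors sqrt(count)
propagated through the normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from shapely.geometry import LineString, Point, Polygon

__all__ = [
    "NuclearOutline",
    "CbdHistogram",
    "resample_polygon",
    "interpolate_outline",
    "compute_cbd",
    "radial_histogram",
]

N_RESAMPLED_VERTICES = 64
CLAMP_TOLERANCE = 1.02  # marginally-outside points (segmentation noise) clamp to 1


def _ensure_ccw(verts: np.ndarray) -> np.ndarray:
    x, y = verts[:, 0], verts[:, 1]
    area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    return verts if area2 > 0 else verts[::-1].copy()


def resample_polygon(verts: np.ndarray, n: int = N_RESAMPLED_VERTICES) -> np.ndarray:
    """Resample a closed polygon to `n` vertices equally spaced by arc length."""
    verts = np.asarray(verts, dtype=float)
    if verts.shape[0] < 3:
        raise ValueError("a polygon needs at least 3 vertices")
    closed = np.vstack([verts, verts[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    arc = np.concatenate(([0.0], np.cumsum(seg)))
    total = arc[-1]
    targets = np.linspace(0.0, total, n, endpoint=False)
    out = np.empty((n, 2))
    out[:, 0] = np.interp(targets, arc, closed[:, 0])
    out[:, 1] = np.interp(targets, arc, closed[:, 1])
    return out


def _align(ref: np.ndarray, other: np.ndarray) -> np.ndarray:
    """Cyclic shift of `other` minimizing the summed vertex distance to `ref`."""
    n = len(ref)
    best_shift, best_cost = 0, np.inf
    for shift in range(n):
        rolled = np.roll(other, -shift, axis=0)
        cost = float(np.sum(np.hypot(*(rolled - ref).T)))
        if cost < best_cost:
            best_cost, best_shift = cost, shift
    return np.roll(other, -best_shift, axis=0)


@dataclass
class NuclearOutline:
    """Keyframe nuclear outlines with per-frame linear interpolation."""

    keyframes: list[tuple[int, np.ndarray]]  # (frame, vertices), sorted by frame

    def __post_init__(self) -> None:
        if len(self.keyframes) < 1:
            raise ValueError("at least one keyframe outline is required")
        self.keyframes = sorted(
            ((int(f), np.asarray(v, dtype=float)) for f, v in self.keyframes),
            key=lambda kv: kv[0],
        )
        resampled = []
        ref = None
        for f, verts in self.keyframes:
            v = _ensure_ccw(resample_polygon(verts))
            if ref is not None:
                v = _align(ref, v)
            resampled.append((f, v))
            ref = v
        self.keyframes = resampled

    @property
    def first_frame(self) -> int:
        return self.keyframes[0][0]

    @property
    def last_frame(self) -> int:
        return self.keyframes[-1][0]


def interpolate_outline(outline: NuclearOutline, frame: int) -> np.ndarray:
    """Vertex-wise linear interpolation between the bracketing keyframes."""
    if not outline.first_frame <= frame <= outline.last_frame:
        raise IndexError(
            f"frame {frame} outside keyframe range "
            f"[{outline.first_frame}, {outline.last_frame}]"
        )
    frames = [f for f, _ in outline.keyframes]
    hi = int(np.searchsorted(frames, frame, side="left"))
    if frames[hi] == frame:
        return outline.keyframes[hi][1].copy()
    f0, v0 = outline.keyframes[hi - 1]
    f1, v1 = outline.keyframes[hi]
    w = (frame - f0) / (f1 - f0)
    return (1.0 - w) * v0 + w * v1


def compute_cbd(
    point: Sequence[float],
    polygon: np.ndarray,
    centroid: Sequence[float] | None = None,
) -> float:
    """Raw center-border distance of a point within a polygon.

    The ray from the centroid through the point is intersected with the
    polygon boundary; the returned ratio |point - centroid| / |border -
    centroid| exceeds 1 for points outside the outline (callers clamp or
    exclude).  The outermost boundary crossing defines the border, which is
    exact for convex outlines.
    """
    poly = Polygon(np.asarray(polygon, dtype=float))
    if centroid is None:
        c = poly.centroid
        centroid = np.array([c.x, c.y])
    else:
        centroid = np.asarray(centroid, dtype=float)
    p = np.asarray(point, dtype=float)
    d = p - centroid
    dist_p = float(np.hypot(*d))
    if dist_p == 0.0:
        return 0.0
    minx, miny, maxx, maxy = poly.bounds
    reach = 4.0 * max(maxx - minx, maxy - miny, dist_p)
    ray = LineString([centroid, centroid + d / dist_p * reach])
    inter = ray.intersection(poly.exterior)
    if inter.is_empty:
        raise ValueError("ray does not intersect the polygon boundary")
    pts = []
    for geom in getattr(inter, "geoms", [inter]):
        if isinstance(geom, Point):
            pts.append((geom.x, geom.y))
        else:  # collinear overlap: take its endpoints
            pts.extend(list(geom.coords))
    border = max(float(np.hypot(x - centroid[0], y - centroid[1])) for x, y in pts)
    return dist_p / border


@dataclass(frozen=True)
class CbdHistogram:
    bin_edges: np.ndarray  # n_bins + 1 edges over [0, 1]
    counts: np.ndarray
    density: np.ndarray  # counts / ring area
    normalized: np.ndarray  # density / max density, max bin = 1
    errors: np.ndarray  # sqrt(count) propagated through the normalization
    n_excluded: int = 0


def radial_histogram(
    cbds: np.ndarray, n_bins: int = 5, clamp_tolerance: float = CLAMP_TOLERANCE
) -> CbdHistogram:
    """Area-normalized radial histogram of CBD values.

    Values in (1, clamp_tolerance] are clamped to 1 (segmentation noise);
    larger values are excluded and counted in ``n_excluded``.
    """
    cbds = np.asarray(cbds, dtype=float)
    keep = cbds <= clamp_tolerance
    n_excluded = int(np.sum(~keep))
    vals = np.minimum(cbds[keep], 1.0)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(vals, bins=edges)
    i = np.arange(n_bins, dtype=float)
    ring_area = ((i + 1) ** 2 - i**2) / n_bins**2  # unit-disk ring areas, sum 1
    density = counts / ring_area
    peak = density.max() if density.max() > 0 else 1.0
    normalized = density / peak
    errors = np.sqrt(counts) / ring_area / peak
    return CbdHistogram(edges, counts, density, normalized, errors, n_excluded)
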