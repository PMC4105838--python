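"""Skeleton-based measurement of segmented root systems.

A binary root mask is thinned to a one-pixel 8-connected centerline,
short terminal spurs (thinning artifacts of a ragged mask boundary) are
pruned, and lengths/diameters are read off the skeleton:

* ``skeleton_length`` - Freeman chain-code length: orthogonal steps count
  1 px, diagonal steps sqrt(2) px.  Simple and oracle-checkable, but it
  systematically overestimates smooth curves digitized on a grid (up to
  ~8% for straight runs near 22.5 deg).
* ``smooth_skeleton_length`` - traces the skeleton into branch polylines,
  smooths each with a short moving average and sums Euclidean segment
  lengths.  This removes the staircase bias and is the headline length
  estimator of the batch pipeline.
* ``diameter_map`` - per-skeleton-pixel diameter from the Euclidean
  distance transform of the mask, d_px = 2*EDT - 1 (half-pixel boundary
  correction on each side).

Roots are classified into user-defined diameter classes; with the default
single edge at 0.5 mm the classes correspond to thin lateral vs thick
axile roots of maize.  Surface and volume derive from a cylinder model per
skeleton step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _sk_skeletonize

from .errors import InvariantError, ParameterError
from .segment import BinaryMask

SQRT2 = math.sqrt(2.0)
_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class Skeleton:
    """One-pixel-wide 8-connected centerline of a binary mask."""

    pixels: np.ndarray
    mm_per_px: float = 0.13

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ParameterError("skeleton must be 2-D")

    def count(self) -> int:
        return int(self.pixels.sum())


@dataclass
class MeasurementReport:
    """Per-image root measurements in physical units."""

    total_length: float  # mm, chain-code metric (partitions exactly into classes)
    smoothed_length: float  # mm, staircase-corrected estimator
    length_by_class: dict[tuple[float, float], float]
    mean_diameter: float  # mm, length-weighted
    surface: float  # mm^2
    volume: float  # mm^3
    axile_length: float  # mm, diameter >= 0.5 mm
    lateral_length: float  # mm, diameter < 0.5 mm

    def as_row(self) -> dict:
        row = {
            "total_length_mm": self.total_length,
            "smoothed_length_mm": self.smoothed_length,
            "mean_diameter_mm": self.mean_diameter,
            "surface_mm2": self.surface,
            "volume_mm3": self.volume,
            "axile_length_mm": self.axile_length,
            "lateral_length_mm": self.lateral_length,
        }
        for (lo, hi), L in self.length_by_class.items():
            hi_s = "inf" if math.isinf(hi) else f"{hi:g}"
            row[f"length_mm_class_{lo:g}_{hi_s}"] = L
        return row


def skeletonize(mask: BinaryMask) -> Skeleton:
    """Topology-preserving 8-connected thinning; empty mask -> empty skeleton."""
    if not mask.mask.any():
        return Skeleton(np.zeros_like(mask.mask), mask.mm_per_px)
    return Skeleton(_sk_skeletonize(mask.mask), mask.mm_per_px)


# ---------------------------------------------------------------------------
# pixel-graph helpers
# ---------------------------------------------------------------------------


def _pixel_set(skel: Skeleton) -> set[tuple[int, int]]:
    return set(zip(*np.nonzero(skel.pixels)))


def _neighbors(p: tuple[int, int], pts: set[tuple[int, int]]):
    r, c = p
    return [(r + dr, c + dc) for dr, dc in _OFFSETS if (r + dr, c + dc) in pts]


def prune(skel: Skeleton, max_spur_px: int) -> Skeleton:
    """Iteratively remove terminal branches shorter than ``max_spur_px``
    that end at a junction; whole components (no junction) are kept."""
    if max_spur_px < 0:
        raise ParameterError("max_spur_px must be >= 0")
    if max_spur_px == 0:
        return Skeleton(skel.pixels.copy(), skel.mm_per_px)
    pts = _pixel_set(skel)
    changed = True
    while changed:
        changed = False
        degree = {p: len(_neighbors(p, pts)) for p in pts}
        endpoints = [p for p, d in degree.items() if d == 1]
        for end in endpoints:
            if end not in pts:
                continue
            path = [end]
            visited = {end}
            spur = None
            while True:
                cur = path[-1]
                if len(path) > 1 and degree.get(cur, 0) >= 3:
                    spur = path[:-1]  # junction itself stays
                    break
                nxt = [n for n in _neighbors(cur, pts) if n not in visited]
                if not nxt:
                    break  # isolated segment: not a spur
                if len(path) >= max_spur_px:
                    break  # already long enough to keep
                path.append(nxt[0])
                visited.add(nxt[0])
            if spur is not None and len(spur) < max_spur_px:
                pts -= set(spur)
                changed = True
    out = np.zeros_like(skel.pixels)
    if pts:
        rr, cc = zip(*pts)
        out[list(rr), list(cc)] = True
        # a removed diagonal spur can leave a redundant bump pixel next to the
        # main line; one re-thinning pass restores strict one-pixel width
        out = _sk_skeletonize(out)
    return Skeleton(out, skel.mm_per_px)


def _edges(skel: Skeleton):
    """Unique 8-adjacent pixel pairs as index arrays.

    Returns (r1, c1, r2, c2, weight_px) with weight 1 for orthogonal and
    sqrt(2) for diagonal steps; each unordered pair appears once.
    """
    s = skel.pixels
    pairs = []
    shifts = [((0, 1), 1.0), ((1, 0), 1.0), ((1, 1), SQRT2), ((1, -1), SQRT2)]
    for (dr, dc), wgt in shifts:
        a = s
        b = np.zeros_like(s)
        if dc >= 0:
            b[: s.shape[0] - dr or None, : s.shape[1] - dc or None] = s[dr:, dc:]
        else:
            b[: s.shape[0] - dr or None, -dc:] = s[dr:, :dc]
        both = a & b
        rr, cc = np.nonzero(both)
        pairs.append((rr, cc, rr + dr, cc + dc, np.full(rr.size, wgt)))
    r1 = np.concatenate([p[0] for p in pairs])
    c1 = np.concatenate([p[1] for p in pairs])
    r2 = np.concatenate([p[2] for p in pairs])
    c2 = np.concatenate([p[3] for p in pairs])
    w = np.concatenate([p[4] for p in pairs])
    return r1, c1, r2, c2, w


def skeleton_length(skel: Skeleton) -> float:
    """Chain-code length in mm: sum over adjacent skeleton-pixel pairs of
    1 (orthogonal) or sqrt(2) (diagonal) pixel units."""
    *_, w = _edges(skel)
    return float(w.sum()) * skel.mm_per_px


def _trace_paths(skel: Skeleton) -> list[np.ndarray]:
    """Decompose the skeleton into branch polylines between nodes
    (endpoints and junctions); isolated cycles are traced too."""
    pts = _pixel_set(skel)
    if not pts:
        return []
    degree = {p: len(_neighbors(p, pts)) for p in pts}
    nodes = {p for p, d in degree.items() if d != 2}
    visited_edges: set[frozenset] = set()
    paths: list[np.ndarray] = []

    def walk(start, first):
        path = [start, first]
        visited_edges.add(frozenset((start, first)))
        while path[-1] not in nodes:
            cur, prev = path[-1], path[-2]
            nxt = [
                n
                for n in _neighbors(cur, pts)
                if n != prev and frozenset((cur, n)) not in visited_edges
            ]
            if not nxt:
                break
            visited_edges.add(frozenset((cur, nxt[0])))
            path.append(nxt[0])
        return path

    for node in sorted(nodes):
        for nb in sorted(_neighbors(node, pts)):
            if frozenset((node, nb)) in visited_edges:
                continue
            paths.append(np.array(walk(node, nb), dtype=float))
    # pure cycles contain no nodes
    seen = set()
    for path in paths:
        seen.update(map(tuple, path.astype(int)))
    for p in sorted(pts - seen - nodes):
        nbs = _neighbors(p, pts)
        if nbs and all(frozenset((p, n)) not in visited_edges for n in nbs):
            paths.append(np.array(walk(p, nbs[0]), dtype=float))
            seen.update(map(tuple, paths[-1].astype(int)))
    return paths


def smooth_skeleton_length(skel: Skeleton, window: int = 5) -> float:
    """Staircase-corrected skeleton length in mm.

    Branch polylines are smoothed with a ``window``-point moving average
    (endpoints pinned) before summing Euclidean segment lengths, removing
    the systematic overestimation of chain-code length on digitized curves.
    """
    if window < 1:
        raise ParameterError("window must be >= 1")
    total = 0.0
    for path in _trace_paths(skel):
        coords = path
        if window > 1 and len(coords) > window:
            sm = ndimage.uniform_filter1d(coords, size=window, axis=0, mode="nearest")
            sm[0], sm[-1] = coords[0], coords[-1]
            coords = sm
        total += float(np.linalg.norm(np.diff(coords, axis=0), axis=1).sum())
    return total * skel.mm_per_px


def diameter_map(mask: BinaryMask, skel: Skeleton) -> np.ndarray:
    """Per-skeleton-pixel root diameter in mm (NaN off the skeleton).

    Diameter at a centerline pixel is (2*EDT - 1) pixels, where EDT is the
    Euclidean distance from the pixel center to the nearest background
    pixel center; the -1 accounts for the half pixel between each boundary
    pixel center and the true object boundary.
    """
    if mask.shape != skel.pixels.shape:
        raise ParameterError("mask and skeleton shapes differ")
    if np.any(skel.pixels & ~mask.mask):
        raise InvariantError("skeleton pixel outside the mask")
    edt = ndimage.distance_transform_edt(mask.mask)
    out = np.full(mask.shape, np.nan)
    sel = skel.pixels
    out[sel] = np.maximum(2.0 * edt[sel] - 1.0, 1.0) * mask.mm_per_px
    return out


def surface_volume(lengths_mm, diameters_mm) -> tuple[float, float]:
    """Cylinder-model totals: surface = sum(pi d L), volume = sum(pi (d/2)^2 L)."""
    L = np.asarray(lengths_mm, dtype=float)
    d = np.asarray(diameters_mm, dtype=float)
    surface = float(np.sum(np.pi * d * L))
    volume = float(np.sum(np.pi * (d / 2.0) ** 2 * L))
    return surface, volume


def length_by_class(
    skel: Skeleton,
    diameters: np.ndarray,
    class_edges: tuple[float, ...] = (0.5,),
    axile_min_diameter: float = 0.5,
    smooth_window: int = 5,
) -> MeasurementReport:
    """Distribute skeleton length over diameter classes.

    Each chain-code step is assigned to the class of its midpoint diameter
    (mean of the two endpoint diameters); classes are the intervals cut at
    ``class_edges``.  ``axile_length``/``lateral_length`` split at
    ``axile_min_diameter`` (thick axile vs thin lateral roots).
    """
    edges = tuple(float(e) for e in class_edges)
    if list(edges) != sorted(set(edges)):
        raise ParameterError("class_edges must be strictly increasing")
    r1, c1, r2, c2, w = _edges(skel)
    mmpp = skel.mm_per_px
    step_mm = w * mmpp
    d_mid = (
        (diameters[r1, c1] + diameters[r2, c2]) / 2.0
        if r1.size
        else np.zeros(0)
    )

    bounds = [0.0, *edges, math.inf]
    by_class: dict[tuple[float, float], float] = {}
    if r1.size:
        which = np.digitize(d_mid, edges)
    for k in range(len(bounds) - 1):
        sel = which == k if r1.size else np.zeros(0, bool)
        by_class[(bounds[k], bounds[k + 1])] = float(step_mm[sel].sum()) if r1.size else 0.0

    total = float(step_mm.sum())
    if r1.size:
        axile = float(step_mm[d_mid >= axile_min_diameter].sum())
        mean_d = float(np.average(d_mid, weights=step_mm)) if total > 0 else 0.0
        surface, volume = surface_volume(step_mm, d_mid)
    else:
        axile, mean_d, surface, volume = 0.0, 0.0, 0.0, 0.0
    return MeasurementReport(
        total_length=total,
        smoothed_length=smooth_skeleton_length(skel, window=smooth_window),
        length_by_class=by_class,
        mean_diameter=mean_d,
        surface=surface,
        volume=volume,
        axile_length=axile,
        lateral_length=total - axile,
    )


def measure_mask(
    mask: BinaryMask,
    prune_px: int = 5,
    class_edges: tuple[float, ...] = (0.5,),
    smooth_window: int = 5,
) -> MeasurementReport:
    """Headline measurement chain: thin, prune spurs, read diameters from
    the distance transform and tabulate lengths by diameter class."""
    skel = prune(skeletonize(mask), prune_px)
    dia = diameter_map(mask, skel)
    return length_by_class(skel, dia, class_edges=class_edges, smooth_window=smooth_window)


# ---------------------------------------------------------------------------
# resolution arithmetic
# ---------------------------------------------------------------------------


def resolution_mm_per_px(imaged_width_mm: float, sensor_px_across: int) -> float:
    """Physical pixel size achieved when ``imaged_width_mm`` of scene spans
    ``sensor_px_across`` sensor pixels."""
    if imaged_width_mm <= 0 or sensor_px_across <= 0:
        raise ParameterError("imaged width and sensor pixels must be positive")
    return imaged_width_mm / sensor_px_across


def min_detectable_diameter(mm_per_px: float, k_px: int = 3) -> float:
    """Smallest root diameter resolvable by image analysis, using the rule
    of thumb that a root must span at least ``k_px`` (default 3) pixels."""
    if mm_per_px <= 0 or k_px <= 0:
        raise ParameterError("mm_per_px and k_px must be positive")
    return k_px * mm_per_px
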