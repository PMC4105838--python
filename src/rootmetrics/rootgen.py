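"""Vector root systems, a minimal root-markup XML format, and artificial
root rendering with exactly known ground-truth length.

The generator emulates young maize root systems growing on a flat
germination sheet: a few thick *axile* roots (primary, seminal, crown;
diameters 0.6-1.2 mm) curve downward from the top edge, and thin *lateral*
roots (diameters 0.26-0.47 mm) branch from arc-length positions along them.

Rendering follows the artificial-root construction used to benchmark root
measurement software: each root's node polyline is interpolated by a spline,
and Gaussian intensity cross-sections are laid along the centerline with the
full width at half maximum (FWHM) of the Gaussian matched to the local root
diameter, i.e. sigma = d / (2*sqrt(2*ln 2)).  Because the centerline is an
analytic spline, the rendered image comes with an exact length in mm and in
pixels - the ground truth against which measurement pipelines are scored.

Coordinates are in mm, origin at the top-left corner, y increasing downward
(image row order).
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

from .errors import (
    InvariantError,
    MarkupParseError,
    MarkupSchemaError,
    ParameterError,
)
from .imaging import RasterImage

#: FWHM of a Gaussian = 2*sqrt(2 ln 2) * sigma
FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))

#: published diameter ranges for maize on paper (mm)
LATERAL_DIAMETER_RANGE = (0.26, 0.47)
AXILE_DIAMETER_RANGE = (0.6, 1.2)


def sigma_from_diameter(diameter_mm: float, mm_per_px: float) -> float:
    """Gaussian sigma (in px) whose FWHM equals the root diameter."""
    return (diameter_mm / mm_per_px) / FWHM_FACTOR


@dataclass(frozen=True)
class RootNode:
    """A traced point on a root centerline with its local diameter (all mm)."""

    x: float
    y: float
    diameter: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise InvariantError("node coordinates must be finite")
        if not (math.isfinite(self.diameter) and self.diameter > 0):
            raise InvariantError(f"node diameter must be positive, got {self.diameter}")


@dataclass
class Root:
    """An ordered node chain; order 0 = axile, order 1 = lateral."""

    id: str
    order: int
    nodes: list[RootNode]
    parent_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.nodes) < 2:
            raise InvariantError(f"root {self.id!r} needs >= 2 nodes")
        if self.order == 1 and self.parent_id is None:
            raise InvariantError(f"lateral root {self.id!r} must declare a parent_id")
        for a, b in zip(self.nodes, self.nodes[1:]):
            if a.x == b.x and a.y == b.y:
                raise InvariantError(f"root {self.id!r} has coincident consecutive nodes")

    @property
    def points(self) -> np.ndarray:
        return np.array([[n.x, n.y] for n in self.nodes], dtype=float)

    @property
    def diameters(self) -> np.ndarray:
        return np.array([n.diameter for n in self.nodes], dtype=float)


@dataclass
class RootSystem:
    """A set of roots inside a rectangular extent (width, height) in mm."""

    roots: list[Root]
    extent: tuple[float, float]
    seed: int | None = None

    def __post_init__(self) -> None:
        w, h = self.extent
        if w <= 0 or h <= 0:
            raise ParameterError("extent must be positive")
        for root in self.roots:
            pts = root.points
            if pts[:, 0].min() < -1e-9 or pts[:, 0].max() > w + 1e-9:
                raise InvariantError(f"root {root.id!r} exceeds extent in x")
            if pts[:, 1].min() < -1e-9 or pts[:, 1].max() > h + 1e-9:
                raise InvariantError(f"root {root.id!r} exceeds extent in y")

    def root_by_id(self, root_id: str) -> Root:
        for r in self.roots:
            if r.id == root_id:
                return r
        raise KeyError(root_id)


@dataclass
class RenderConfig:
    """Rendering parameters for artificial root images.

    ``ragged_edges`` adds seeded jitter (sd = 20% of the local diameter) to
    the rendered width along the centerline, emulating root hairs and
    reflections that give real segmentations a ragged boundary.
    """

    mm_per_px: float = 0.13
    foreground_amplitude: float = 200.0
    background_level: float = 40.0
    noise_sd: float = 0.0
    ragged_edges: bool = False
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if self.mm_per_px <= 0:
            raise ParameterError("mm_per_px must be positive")
        maxv = 2**self.bit_depth - 1
        if not (0 <= self.background_level <= maxv) or not (
            0 <= self.foreground_amplitude <= maxv
        ):
            raise ParameterError(f"tonal levels must lie in [0, {maxv}]")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Exact per-root and total lengths attached to a rendered image."""

    per_root: pd.DataFrame  # columns: id, order, length_mm, length_px, mean_diameter_mm
    total_length_mm: float
    total_length_px: float
    mm_per_px: float
    warnings: list[str] = field(default_factory=list)

    def to_csv(self, path: str | Path) -> None:
        self.per_root.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# spline machinery
# ---------------------------------------------------------------------------


def _chord_param(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _centerline_spline(root: Root):
    """Chord-length-parameterized interpolant through the nodes.

    Natural cubic for >= 4 nodes, piecewise linear otherwise.  Returns
    (evaluate(t) -> (n,2) points, node parameter values).
    """
    pts = root.points
    t = _chord_param(pts)
    if len(pts) >= 4:
        spline = CubicSpline(t, pts, bc_type="natural", axis=0)
        return spline, t
    def linear(u):
        u = np.atleast_1d(np.asarray(u, dtype=float))
        x = np.interp(u, t, pts[:, 0])
        y = np.interp(u, t, pts[:, 1])
        return np.stack([x, y], axis=-1)
    return linear, t


def resample_centerline(root: Root, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Densely sample a root's interpolating spline.

    Returns (points, diameters): points is an (n, 2) mm array whose spacing
    is <= ``step`` with both endpoints preserved exactly; diameters are
    interpolated along the curve between the node diameters.
    """
    if step <= 0:
        raise ParameterError("step must be positive")
    spline, t = _centerline_spline(root)
    total = t[-1]
    # oversample in parameter so that arc spacing stays comfortably under step
    n = max(int(math.ceil(4.0 * total / step)), len(t)) + 1
    u = np.linspace(0.0, total, n)
    u = np.unique(np.concatenate([u, t]))  # pass exactly through the nodes
    pts = np.asarray(spline(u), dtype=float)
    dia = np.interp(u, t, root.diameters)
    return pts, dia


def _arc_length(points: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def true_length(system: RootSystem, step: float = 0.02) -> tuple[dict[str, float], float]:
    """Exact (spline-integrated) per-root and total length in mm."""
    per_root = {}
    for root in system.roots:
        pts, _ = resample_centerline(root, step)
        per_root[root.id] = _arc_length(pts)
    return per_root, float(sum(per_root.values()))


# ---------------------------------------------------------------------------
# system generation
# ---------------------------------------------------------------------------


def generate_root_system(
    n_axile: int,
    laterals_per_cm: float,
    extent: tuple[float, float],
    seed: int,
) -> RootSystem:
    """Generate a reproducible synthetic root system.

    Axile roots start near the top edge and random-walk downward with gentle
    curvature; laterals attach exactly on their parent's centerline spline at
    Poisson-distributed arc positions (rate ``laterals_per_cm``), branch
    sideways and drift back toward vertical (gravitropism).
    """
    if n_axile < 1:
        raise ParameterError("n_axile must be >= 1")
    if laterals_per_cm < 0:
        raise ParameterError("laterals_per_cm must be >= 0")
    w, h = extent
    if w <= 0 or h <= 0:
        raise ParameterError("extent must be positive")

    rng = np.random.default_rng(seed)
    margin = 1.5
    roots: list[Root] = []

    for i in range(n_axile):
        d = float(rng.uniform(*AXILE_DIAMETER_RANGE))
        x = (i + 0.5) / n_axile * w + float(rng.normal(0, w * 0.03))
        x = min(max(x, margin), w - margin)
        y = margin
        theta = float(rng.normal(0.0, 0.10))  # angle from vertical, radians
        nodes = [RootNode(x, y, d)]
        step_mm = 6.0
        while y < h - margin - 1e-9:
            theta = float(np.clip(theta + rng.normal(0.0, 0.12), -0.45, 0.45))
            nx = x + step_mm * math.sin(theta)
            ny = y + step_mm * math.cos(theta)
            if nx < margin or nx > w - margin:
                theta = -theta
                nx = x + step_mm * math.sin(theta)
            nx = min(max(nx, margin), w - margin)
            if ny > h - margin:
                # shorten the final step to land on the bottom margin
                frac = (h - margin - y) / (ny - y)
                nx = x + frac * (nx - x)
                ny = h - margin
            if abs(nx - x) < 1e-9 and abs(ny - y) < 1e-9:
                break
            nodes.append(RootNode(float(nx), float(ny), d))
            x, y = nx, ny
        axile = Root(id=f"A{i + 1}", order=0, nodes=nodes)
        roots.append(axile)

        if laterals_per_cm <= 0:
            continue
        spline, t = _centerline_spline(axile)
        arc_cm = t[-1] / 10.0
        n_lat = int(rng.poisson(laterals_per_cm * arc_cm))
        made = 0
        for _ in range(n_lat):
            s = float(rng.uniform(0.05, 0.95)) * t[-1]
            p0 = np.asarray(spline(s)).reshape(-1)
            # tangent by central difference on the spline parameter
            eps = min(1e-3, t[-1] * 1e-4)
            tang = (np.asarray(spline(s + eps)) - np.asarray(spline(s - eps))).reshape(-1)
            tang /= np.linalg.norm(tang)
            side = 1.0 if rng.random() < 0.5 else -1.0
            phi = float(rng.uniform(math.radians(45), math.radians(80)))
            # rotate tangent by +/- phi to get the emergence direction
            c, sn = math.cos(side * phi), math.sin(side * phi)
            direction = np.array(
                [c * tang[0] - sn * tang[1], sn * tang[0] + c * tang[1]]
            )
            d_lat = float(rng.uniform(*LATERAL_DIAMETER_RANGE))
            total_len = float(rng.uniform(8.0, 20.0))
            n_seg = 4
            seg = total_len / n_seg
            lat_pts = [p0.copy()]
            p = p0.copy()
            ang = math.atan2(direction[0], direction[1])  # from vertical
            for _k in range(n_seg):
                # mild gravitropism: laterals keep an oblique course, bending
                # slowly toward vertical rather than collapsing onto the parent
                ang = 0.92 * ang + float(rng.normal(0.0, 0.08))
                p = p + seg * np.array([math.sin(ang), math.cos(ang)])
                lat_pts.append(p.copy())
            # keep the in-extent prefix
            kept = [lat_pts[0]]
            for p in lat_pts[1:]:
                if margin / 2 <= p[0] <= w - margin / 2 and margin / 2 <= p[1] <= h - margin / 2:
                    kept.append(p)
                else:
                    break
            if len(kept) < 2:
                continue
            made += 1
            lat_nodes = [RootNode(float(px), float(py), d_lat) for px, py in kept]
            roots.append(
                Root(id=f"{axile.id}.L{made}", order=1, nodes=lat_nodes, parent_id=axile.id)
            )

    return RootSystem(roots=roots, extent=(float(w), float(h)), seed=seed)


# ---------------------------------------------------------------------------
# markup I/O
# ---------------------------------------------------------------------------

_PRECISION = 6


def write_root_markup(system: RootSystem) -> str:
    """Serialize a RootSystem to the toolkit's minimal root-markup XML."""
    fmt = f"{{:.{_PRECISION}f}}"
    scene = ET.Element(
        "rootsystem",
        {
            "width_mm": fmt.format(system.extent[0]),
            "height_mm": fmt.format(system.extent[1]),
        },
    )
    if system.seed is not None:
        scene.set("seed", str(system.seed))
    for root in system.roots:
        attrs = {"id": root.id, "order": str(root.order)}
        if root.parent_id is not None:
            attrs["parent"] = root.parent_id
        el = ET.SubElement(scene, "root", attrs)
        for node in root.nodes:
            ET.SubElement(
                el,
                "point",
                {
                    "x": fmt.format(node.x),
                    "y": fmt.format(node.y),
                    "diameter": fmt.format(node.diameter),
                },
            )
    ET.indent(scene)
    return ET.tostring(scene, encoding="unicode") + "\n"


def parse_root_markup(document: str) -> RootSystem:
    """Parse the root-markup XML produced by :func:`write_root_markup`."""
    try:
        scene = ET.fromstring(document)
    except ET.ParseError as exc:
        raise MarkupParseError(f"malformed XML: {exc}") from exc
    if scene.tag != "rootsystem":
        raise MarkupSchemaError(f"expected <rootsystem> document, got <{scene.tag}>")
    try:
        extent = (float(scene.get("width_mm")), float(scene.get("height_mm")))
    except (TypeError, ValueError) as exc:
        raise MarkupSchemaError("<rootsystem> needs numeric width_mm/height_mm") from exc
    seed = scene.get("seed")
    roots = []
    for el in scene.findall("root"):
        rid = el.get("id")
        if rid is None:
            raise MarkupSchemaError("<root> element missing id attribute")
        order = int(el.get("order", "0"))
        parent = el.get("parent")
        nodes = []
        for pt in el.findall("point"):
            dia = pt.get("diameter")
            if dia is None:
                raise MarkupSchemaError(f"<point> in root {rid!r} missing diameter attribute")
            try:
                node = RootNode(float(pt.get("x")), float(pt.get("y")), float(dia))
            except (TypeError, ValueError) as exc:
                raise MarkupSchemaError(f"invalid <point> in root {rid!r}: {exc}") from exc
            except InvariantError as exc:
                raise MarkupSchemaError(f"invalid <point> in root {rid!r}: {exc}") from exc
            nodes.append(node)
        try:
            roots.append(Root(id=rid, order=order, nodes=nodes, parent_id=parent))
        except InvariantError as exc:
            raise MarkupSchemaError(str(exc)) from exc
    return RootSystem(roots=roots, extent=extent, seed=int(seed) if seed else None)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def render(
    system: RootSystem, config: RenderConfig | None = None
) -> tuple[RasterImage, GroundTruth]:
    """Render an artificial root image plus its exact ground truth.

    Pixel intensity = background_level + foreground contribution of the
    nearest centerline point, amp * exp(-r^2 / (2 sigma^2)) with
    sigma = diameter / (2 sqrt(2 ln 2)) so the profile FWHM equals the local
    diameter.  Overlapping roots composite by maximum (opaque root over
    paper).  Optional Gaussian sensor noise and ragged-edge width jitter are
    seeded from the system seed.
    """
    config = config or RenderConfig()
    if not system.roots:
        raise ParameterError("cannot render an empty root system")
    mmpp = config.mm_per_px
    w_px = int(math.ceil(system.extent[0] / mmpp))
    h_px = int(math.ceil(system.extent[1] / mmpp))
    fg = np.zeros((h_px, w_px), dtype=float)
    rng = np.random.default_rng(0 if system.seed is None else system.seed)

    warnings: list[str] = []
    rows = []
    step_mm = 0.25 * mmpp
    for root in system.roots:
        pts_mm, dia_mm = resample_centerline(root, step_mm)
        length_mm = _arc_length(pts_mm)
        rows.append(
            {
                "id": root.id,
                "order": root.order,
                "length_mm": length_mm,
                "length_px": length_mm / mmpp,
                "mean_diameter_mm": float(dia_mm.mean()),
            }
        )
        if dia_mm.min() < mmpp:
            warnings.append(
                f"root {root.id}: diameter {dia_mm.min():.3f} mm is below one pixel "
                f"({mmpp:.3f} mm) - sub-resolution root"
            )
        dia_render = dia_mm
        if config.ragged_edges:
            jitter = rng.normal(0.0, 0.2, size=dia_mm.shape)
            dia_render = np.maximum(dia_mm * (1.0 + jitter), 0.05 * dia_mm)
        sigma_px = (dia_render / mmpp) / FWHM_FACTOR

        pts_px = pts_mm / mmpp  # (x, y) in pixel units
        tree = cKDTree(pts_px)
        reach = float(4.0 * sigma_px.max() + 1.0)
        c0 = max(int(pts_px[:, 0].min() - reach), 0)
        c1 = min(int(pts_px[:, 0].max() + reach) + 1, w_px)
        r0 = max(int(pts_px[:, 1].min() - reach), 0)
        r1 = min(int(pts_px[:, 1].max() + reach) + 1, h_px)
        if c0 >= c1 or r0 >= r1:
            continue
        cc, rr = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
        centers = np.stack([cc.ravel() + 0.5, rr.ravel() + 0.5], axis=1)
        dist, idx = tree.query(centers, distance_upper_bound=reach)
        ok = np.isfinite(dist)
        contrib = np.zeros(centers.shape[0])
        sig = sigma_px[np.clip(idx[ok], 0, len(sigma_px) - 1)]
        contrib[ok] = config.foreground_amplitude * np.exp(
            -(dist[ok] ** 2) / (2.0 * sig**2)
        )
        patch = contrib.reshape(r1 - r0, c1 - c0)
        np.maximum(fg[r0:r1, c0:c1], patch, out=fg[r0:r1, c0:c1])

    img = config.background_level + fg
    if config.noise_sd > 0:
        img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 2**config.bit_depth - 1)

    per_root = pd.DataFrame(rows)
    gt = GroundTruth(
        per_root=per_root,
        total_length_mm=float(per_root["length_mm"].sum()),
        total_length_px=float(per_root["length_px"].sum()),
        mm_per_px=mmpp,
        warnings=warnings,
    )
    return RasterImage(img, bit_depth=config.bit_depth, mm_per_px=mmpp), gt
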