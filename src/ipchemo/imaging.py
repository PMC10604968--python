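"""Vessel-network imaging: raster segmentation and synthetic fixtures.

The tumor vasculature enters the model as a set of closed lumen polygons
with tagged inlet/outlet terminals. Real micrographs are segmented with
histogram equalization followed by thresholding and contour extraction;
for testing and for fully reproducible runs a synthetic branched network
is generated inside the tumor ellipse and can be rasterized back to an
image, giving a closed round-trip (generate -> rasterize -> binarize ->
extract) with known ground truth.

Coordinates are millimetres throughout this module. The raster convention
is ``x = origin[0] + col * pixel_size``, ``y = origin[1] + row * pixel_size``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import unary_union
from skimage import exposure, filters, measure

from .errors import (
    GeometryInfeasibleError,
    NoForegroundError,
    NoVesselsError,
    UnderResolvedError,
)

__all__ = [
    "RasterImage",
    "Terminal",
    "VesselNetwork",
    "equalize_and_binarize",
    "extract_vessel_network",
    "generate_synthetic_network",
    "rasterize_network",
    "assign_terminals",
    "read_network",
    "write_network",
]


@dataclass
class RasterImage:
    """A scalar intensity grid with physical pixel size.

    Parameters
    ----------
    pixels : ndarray
        2D grayscale or 3D RGB intensity array; finite values.
    pixel_size : float
        Physical edge length of one pixel in mm.
    origin : tuple of float
        (x, y) mm coordinates of the centre of pixel ``[0, 0]``.
    """

    pixels: np.ndarray
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.size == 0:
            raise ValueError("image must be nonempty")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image intensities must be finite")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    @property
    def gray(self) -> np.ndarray:
        """Grayscale float view in [0, 1]."""
        px = self.pixels
        if px.ndim == 3:  # RGB(A): luminance weights
            px = px[..., :3] @ np.array([0.2125, 0.7154, 0.0721])
        px = px.astype(float)
        lo, hi = px.min(), px.max()
        if hi > 1.0 or lo < 0.0:
            px = (px - lo) / (hi - lo) if hi > lo else np.zeros_like(px)
        return px


@dataclass
class Terminal:
    """An open vessel end on a lumen boundary.

    ``segment`` is a (2, 2) array of the end-cap endpoints in mm; ``role``
    is ``"inlet"`` or ``"outlet"``.
    """

    segment: np.ndarray
    role: str
    label: str

    def __post_init__(self):
        self.segment = np.asarray(self.segment, dtype=float).reshape(2, 2)
        if self.role not in ("inlet", "outlet"):
            raise ValueError(f"terminal role must be inlet/outlet, got {self.role!r}")

    @property
    def midpoint(self) -> np.ndarray:
        return self.segment.mean(axis=0)


@dataclass
class VesselNetwork:
    """Lumen polygons (mm) plus tagged inlet/outlet terminals."""

    polygons: list[Polygon]
    terminals: list[Terminal] = field(default_factory=list)
    channel_width: float | None = None

    def __post_init__(self):
        for p in self.polygons:
            if not p.is_valid:
                raise ValueError("lumen polygons must be simple (non-self-intersecting)")

    @property
    def total_area(self) -> float:
        return float(sum(p.area for p in self.polygons))

    @property
    def inlets(self) -> list[Terminal]:
        return [t for t in self.terminals if t.role == "inlet"]

    @property
    def outlets(self) -> list[Terminal]:
        return [t for t in self.terminals if t.role == "outlet"]

    def union(self) -> Polygon:
        return unary_union(self.polygons)

    def estimate_channel_width(self) -> float:
        """Width scale of the channels, 2A/(P/2) for ribbon-like lumens."""
        if self.channel_width is not None:
            return self.channel_width
        area = self.total_area
        per = sum(p.exterior.length for p in self.polygons)
        if per == 0:
            return 0.0
        return 4.0 * area / per

    def validate_terminals(self, tol: float | None = None) -> None:
        """Check every terminal midpoint lies on a lumen boundary."""
        if not self.inlets or not self.outlets:
            raise ValueError("network needs at least one inlet and one outlet")
        tol = tol if tol is not None else 0.25 * (self.estimate_channel_width() or 1.0)
        boundary = unary_union([p.exterior for p in self.polygons])
        for t in self.terminals:
            if boundary.distance(Point(t.midpoint)) > tol:
                raise ValueError(f"terminal {t.label} does not lie on a lumen boundary")


def equalize_and_binarize(
    image: RasterImage,
    threshold_policy: str = "otsu",
    fixed_threshold: float = 0.5,
    smooth_sigma_px: float = 1.0,
) -> np.ndarray:
    """Histogram-equalize an image and threshold it into a vessel mask.

    Foreground (True) is the bright phase. The image is lightly smoothed
    (``smooth_sigma_px``), histogram-equalized for contrast normalization,
    and thresholded. Because global equalization flattens the histogram (a
    flat histogram has no Otsu optimum), the Otsu class statistics are
    computed in the smoothed original-intensity domain and the threshold is
    mapped through the (monotone) equalization, which yields an identical
    partition. With the ``otsu`` policy a zero-contrast image is an error
    (there is nothing to separate); with ``fixed`` it yields an
    all-background mask; the fixed threshold applies to the equalized
    intensities in [0, 1].
    """
    gray = image.gray
    if np.ptp(gray) == 0:
        if threshold_policy == "otsu":
            raise NoForegroundError("no-foreground: constant-intensity image")
        return np.zeros(gray.shape, dtype=bool)
    if smooth_sigma_px > 0:
        from scipy.ndimage import gaussian_filter

        gray = gaussian_filter(gray, smooth_sigma_px)
    eq = exposure.equalize_hist(gray)
    if threshold_policy == "otsu":
        thr = filters.threshold_otsu(gray)
        mask = gray > thr
    elif threshold_policy == "fixed":
        mask = eq > fixed_threshold
    else:
        raise ValueError(f"unknown threshold policy {threshold_policy!r}")
    if threshold_policy == "otsu" and not mask.any():
        raise NoForegroundError("no-foreground: threshold removed all pixels")
    return mask


def extract_vessel_network(
    mask: np.ndarray,
    pixel_size: float,
    min_area: float = 0.0,
    origin: tuple[float, float] = (0.0, 0.0),
    simplify_tol_px: float = 0.2,
) -> VesselNetwork:
    """Trace closed lumen polygons from a binary vessel mask.

    Connected components smaller than ``min_area`` (mm^2) are discarded.
    Component outlines are traced at the half-level of the padded mask and
    lightly simplified with Douglas-Peucker (``simplify_tol_px``) to drop
    collinear vertices; the mesher resamples wall polylines anyway, so no
    aggressive simplification is needed. Terminals are left unassigned.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise NoVesselsError("no-vessels: mask is empty")
    labels = measure.label(mask, connectivity=2)
    polygons: list[Polygon] = []
    for region in measure.regionprops(labels):
        if region.area * pixel_size**2 < min_area:
            continue
        comp = np.pad(labels == region.label, 1).astype(float)
        contours = measure.find_contours(comp, 0.5)
        if not contours:
            continue
        contour = max(contours, key=len)  # outer boundary of the component
        contour = measure.approximate_polygon(contour, tolerance=simplify_tol_px)
        rows, cols = contour[:, 0] - 1.0, contour[:, 1] - 1.0
        xy = np.column_stack(
            [origin[0] + cols * pixel_size, origin[1] + rows * pixel_size]
        )
        if len(xy) < 4:
            continue
        poly = Polygon(xy)
        if not poly.is_valid:
            poly = poly.buffer(0)
            if poly.is_empty:
                continue
            if poly.geom_type == "MultiPolygon":
                poly = max(poly.geoms, key=lambda g: g.area)
        polygons.append(poly)
    if not polygons:
        raise NoVesselsError("no-vessels: no component above the area floor")
    return VesselNetwork(polygons=polygons)


def _jittered_angles(lo: float, hi: float, n: int, rng: np.random.Generator) -> np.ndarray:
    if n == 1:
        base = np.array([(lo + hi) / 2.0])
    else:
        base = np.linspace(lo, hi, n)
        base = base + rng.uniform(-0.25, 0.25, n) * (hi - lo) / max(n - 1, 1)
    return np.deg2rad(base)


def _clip_inside(p: np.ndarray, a: float, b: float, factor: float) -> np.ndarray:
    r = np.hypot(p[0] / a, p[1] / b)
    if r > factor:
        p = p * (factor / r)
    return p


def generate_synthetic_network(
    n_inlets: int = 5,
    n_outlets: int = 6,
    semi_axes: tuple[float, float] = (2.425, 1.755),
    channel_width: float = 0.05,
    seed: int = 0,
    boundary_factor: float = 0.85,
) -> VesselNetwork:
    """Generate a branched vessel tree inside the tumor ellipse.

    Inlet terminals are placed near the left half of the ellipse boundary
    and outlets near the right half (at ``boundary_factor`` of the boundary
    radius, so terminal stubs approach but never cross the surface). Each
    terminal connects through a jittered intermediate point to one of two
    interior hubs joined by a trunk channel, and the whole polyline tree is
    dilated to ``channel_width``. Deterministic for a given seed.
    """
    a, b = semi_axes
    if n_inlets < 1 or n_outlets < 1:
        raise ValueError("need at least one inlet and one outlet")
    if channel_width >= min(a, b):
        raise GeometryInfeasibleError(
            "geometry-infeasible: channel width exceeds the minor semi-axis"
        )
    # crude packing bound: terminals on each half-perimeter need ~3 widths each
    half_perimeter = np.pi * boundary_factor * (a + b) / 2.0
    if 3.0 * channel_width * max(n_inlets, n_outlets) > half_perimeter:
        raise GeometryInfeasibleError(
            "geometry-infeasible: too many terminals for this ellipse/width"
        )
    rng = np.random.default_rng(seed)
    th_in = _jittered_angles(115.0, 245.0, n_inlets, rng)
    th_out = _jittered_angles(-65.0, 65.0, n_outlets, rng)
    f = boundary_factor
    hub_l = np.array([-0.30 * a, 0.0])
    hub_r = np.array([0.30 * a, 0.0])

    lines: list[LineString] = [LineString([hub_l, hub_r])]
    terminals: list[Terminal] = []

    def _branch(theta: float, hub: np.ndarray, role: str, label: str) -> None:
        tip = np.array([f * a * np.cos(theta), f * b * np.sin(theta)])
        mid = 0.5 * (tip + hub)
        jitter = rng.uniform(-0.12, 0.12) * b
        mid = _clip_inside(mid + np.array([0.0, jitter]), a, b, 0.75)
        lines.append(LineString([tip, mid, hub]))
        d = tip - mid
        d = d / np.linalg.norm(d)
        perp = np.array([-d[1], d[0]])
        seg = np.stack([tip - 0.5 * channel_width * perp, tip + 0.5 * channel_width * perp])
        terminals.append(Terminal(segment=seg, role=role, label=label))

    for i, th in enumerate(th_in):
        _branch(th, hub_l, "inlet", f"Inlet{i + 1}")
    for i, th in enumerate(th_out):
        _branch(th, hub_r, "outlet", f"Outlet{i + 1}")

    tree = unary_union(lines)
    lumen = tree.buffer(channel_width / 2.0, cap_style="flat", join_style="round", quad_segs=8)
    if lumen.geom_type == "MultiPolygon":
        lumen = max(lumen.geoms, key=lambda g: g.area)
    ellipse = shapely.affinity.scale(Point(0, 0).buffer(1.0, quad_segs=128), a, b)
    if not lumen.within(ellipse):
        raise GeometryInfeasibleError(
            "geometry-infeasible: dilated network crosses the ellipse boundary"
        )
    return VesselNetwork(polygons=[lumen], terminals=terminals, channel_width=channel_width)


def rasterize_network(
    network: VesselNetwork,
    pixel_size: float,
    noise_sigma: float = 0.0,
    seed: int = 0,
    margin_px: int = 5,
    bbox: tuple[float, float, float, float] | None = None,
) -> tuple[RasterImage, np.ndarray]:
    """Render a network as an intensity image plus its ground-truth mask.

    Raises an ``under-resolved`` error when the channel width spans fewer
    than 3 pixels; otherwise foreground pixels are those whose centres fall
    inside a lumen polygon, with optional additive Gaussian noise.
    """
    width = network.estimate_channel_width()
    if network.polygons and width > 0 and pixel_size > width / 3.0:
        raise UnderResolvedError(
            f"under-resolved: pixel_size {pixel_size} > channel_width/3 = {width / 3.0:.4g}"
        )
    if bbox is None:
        if network.polygons:
            x0, y0, x1, y1 = unary_union(network.polygons).bounds
        else:
            x0, y0, x1, y1 = 0.0, 0.0, pixel_size * 9, pixel_size * 9
        m = margin_px * pixel_size
        x0, y0, x1, y1 = x0 - m, y0 - m, x1 + m, y1 + m
    else:
        x0, y0, x1, y1 = bbox
    nx = max(int(np.ceil((x1 - x0) / pixel_size)) + 1, 2)
    ny = max(int(np.ceil((y1 - y0) / pixel_size)) + 1, 2)
    xs = x0 + np.arange(nx) * pixel_size
    ys = y0 + np.arange(ny) * pixel_size
    XX, YY = np.meshgrid(xs, ys)
    if network.polygons:
        geom = unary_union(network.polygons)
        mask = shapely.contains_xy(geom, XX.ravel(), YY.ravel()).reshape(ny, nx)
    else:
        mask = np.zeros((ny, nx), dtype=bool)
    pixels = np.where(mask, 0.85, 0.15)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        pixels = np.clip(pixels + noise_sigma * rng.standard_normal(pixels.shape), 0.0, 1.0)
    return RasterImage(pixels=pixels, pixel_size=pixel_size, origin=(x0, y0)), mask


def assign_terminals(
    network: VesselNetwork,
    points: list[tuple[float, float]],
    roles: list[str],
    labels: list[str] | None = None,
    cap_width: float | None = None,
) -> VesselNetwork:
    """Attach terminals to a network by snapping points to lumen boundaries.

    Terminal placement on a segmented image cannot be automated reliably,
    so inlet/outlet locations are supplied (typically from config) and each
    is snapped to the nearest polygon-boundary point; the end-cap segment is
    taken tangent to the boundary there.
    """
    if labels is None:
        counts = {"inlet": 0, "outlet": 0}
        labels = []
        for r in roles:
            counts[r] += 1
            labels.append(f"{r.capitalize()}{counts[r]}")
    w = cap_width or network.estimate_channel_width() or 0.05
    boundary = unary_union([p.exterior for p in network.polygons])
    terminals = []
    for pt, role, label in zip(points, roles, labels):
        p = Point(pt)
        s = boundary.interpolate(boundary.project(p))
        # local tangent via a small parameter step
        eps = 1e-3 * max(w, 1e-6)
        s2 = boundary.interpolate((boundary.project(p) + eps) % boundary.length)
        t = np.array([s2.x - s.x, s2.y - s.y])
        n = np.linalg.norm(t)
        t = t / n if n > 0 else np.array([1.0, 0.0])
        c = np.array([s.x, s.y])
        seg = np.stack([c - 0.5 * w * t, c + 0.5 * w * t])
        terminals.append(Terminal(segment=seg, role=role, label=label))
    return VesselNetwork(
        polygons=network.polygons, terminals=terminals, channel_width=network.channel_width
    )


def write_network(network: VesselNetwork, path) -> None:
    """Write a network as GeoJSON-style structured text."""
    features = [
        {
            "type": "Feature",
            "geometry": {
                "type": "Polygon",
                "coordinates": [list(map(list, p.exterior.coords))],
            },
            "properties": {"kind": "lumen"},
        }
        for p in network.polygons
    ]
    for t in network.terminals:
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "LineString", "coordinates": t.segment.tolist()},
                "properties": {"kind": "terminal", "role": t.role, "label": t.label},
            }
        )
    doc = {
        "type": "FeatureCollection",
        "features": features,
        "properties": {"channel_width": network.channel_width, "units": "mm"},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_network(path) -> VesselNetwork:
    with open(path) as fh:
        doc = json.load(fh)
    polygons, terminals = [], []
    for feat in doc["features"]:
        kind = feat["properties"].get("kind")
        if kind == "lumen":
            polygons.append(Polygon(feat["geometry"]["coordinates"][0]))
        elif kind == "terminal":
            terminals.append(
                Terminal(
                    segment=np.asarray(feat["geometry"]["coordinates"]),
                    role=feat["properties"]["role"],
                    label=feat["properties"]["label"],
                )
            )
    return VesselNetwork(
        polygons=polygons,
        terminals=terminals,
        channel_width=doc.get("properties", {}).get("channel_width"),
    )
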