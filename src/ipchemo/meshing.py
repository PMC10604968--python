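"""Boundary-layer triangular meshing of the tumor domain.

Steep gradients develop at the tumor surface (drug enters there) and at
the vessel walls (fluid/drug exchange), so both are wrapped in graded
boundary layers: a structured band of quad-split triangle layers along the
outer ellipse (geometric growth, default 21 layers with ratio 1.2), and
graded offset point rings along the vessel walls. Everything else is free
triangles from a Delaunay triangulation of graded point sets. Lumens are
meshed too, sharing conforming interfaces with the tissue so wall fluxes
couple the intravascular and interstitial solves.

Node coordinates are millimetres; solvers convert to SI on entry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import Polygon
from shapely.geometry.polygon import orient
from shapely.ops import unary_union

from .errors import MeshFailureError
from .geometry import TumorGeometry

logger = logging.getLogger(__name__)

__all__ = ["SimMesh", "MeshControls", "generate_mesh", "layer_thicknesses", "rectangle_channel_mesh"]

TISSUE, LUMEN = 0, 1


def layer_thicknesses(band: float, n_layers: int, growth: float) -> np.ndarray:
    """Thicknesses of a geometric boundary-layer stack summing to ``band``.

    Layer i has thickness ``t1 * growth**i`` with ``t1`` chosen so the n
    layers exactly span ``band``.
    """
    if n_layers < 1 or band <= 0:
        raise ValueError("need n_layers >= 1 and band > 0")
    if abs(growth - 1.0) < 1e-12:
        return np.full(n_layers, band / n_layers)
    t1 = band * (growth - 1.0) / (growth**n_layers - 1.0)
    return t1 * growth ** np.arange(n_layers)


@dataclass
class MeshControls:
    """Mesh density and boundary-layer controls (lengths in mm)."""

    h_interior: float = 0.08
    n_bl_layers: int = 21
    bl_growth: float = 1.2
    surface_band_frac: float = 0.10  # band width as fraction of minor semi-axis
    n_wall_layers: int = 6
    wall_band_factor: float = 0.35  # band width as multiple of channel width
    h_wall: float | None = None  # along-wall spacing; default channel_width / 4
    h_lumen: float | None = None  # lumen-interior spacing; default channel_width / 4
    quality_floor_deg: float = 2.0  # min angle floor for free triangles


@dataclass
class SimMesh:
    """Conforming triangle mesh with region and boundary tags."""

    nodes: np.ndarray                  # (n, 2) mm
    triangles: np.ndarray              # (m, 3) int
    region: np.ndarray                 # (m,) TISSUE or LUMEN
    boundary_edges: np.ndarray         # (k, 2) node indices
    boundary_tags: np.ndarray          # (k,) str
    is_layer: np.ndarray               # (m,) bool, structured boundary-layer triangles
    terminal_roles: dict[str, str] = field(default_factory=dict)
    geometry: TumorGeometry | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def areas(self) -> np.ndarray:
        """Signed triangle areas (positive for a valid mesh), mm^2."""
        p = self.nodes[self.triangles]
        u, v = p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]
        return 0.5 * (u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0])

    def total_area(self) -> float:
        return float(self.areas().sum())

    def edges_with(self, tag: str) -> np.ndarray:
        return self.boundary_edges[self.boundary_tags == tag]

    def boundary_nodes(self, tag: str) -> np.ndarray:
        return np.unique(self.edges_with(tag))

    def min_angle_deg(self, free_only: bool = True) -> float:
        tris = self.triangles[~self.is_layer] if free_only else self.triangles
        if len(tris) == 0:
            return 90.0
        p = self.nodes[tris]
        ang = []
        for i in range(3):
            u = p[:, (i + 1) % 3] - p[:, i]
            v = p[:, (i + 2) % 3] - p[:, i]
            c = (u * v).sum(1) / (np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
            ang.append(np.degrees(np.arccos(np.clip(c, -1, 1))))
        return float(np.min(ang))

    def validate(self) -> None:
        a = self.areas()
        if np.any(a <= 0):
            raise MeshFailureError(f"mesh-failure: {np.sum(a <= 0)} non-positive elements")
        if len(self.boundary_edges) != len(self.boundary_tags):
            raise MeshFailureError("mesh-failure: facet/tag count mismatch")


def _resample_closed(coords: np.ndarray, h: float) -> np.ndarray:
    """Resample a closed polyline at ~uniform arclength spacing h."""
    seg = np.diff(np.vstack([coords, coords[:1]]), axis=0)
    ds = np.hypot(seg[:, 0], seg[:, 1])
    s = np.concatenate([[0.0], np.cumsum(ds)])
    total = s[-1]
    n = max(int(round(total / h)), 8)
    t = np.linspace(0.0, total, n, endpoint=False)
    pts = np.vstack([coords, coords[:1]])
    x = np.interp(t, s, pts[:, 0])
    y = np.interp(t, s, pts[:, 1])
    return np.column_stack([x, y])


def _closed_normals(pts: np.ndarray) -> np.ndarray:
    """Outward normals of a CCW closed polyline (right of the tangent)."""
    nxt = np.roll(pts, -1, axis=0)
    prv = np.roll(pts, 1, axis=0)
    t = nxt - prv
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    return np.column_stack([t[:, 1], -t[:, 0]])


def _ellipse_ring(a: float, b: float, n: int) -> tuple[np.ndarray, np.ndarray]:
    """n equal-arclength points on the ellipse and their outward normals."""
    th = np.linspace(0, 2 * np.pi, 4096, endpoint=False)
    pts = np.column_stack([a * np.cos(th), b * np.sin(th)])
    ds = np.hypot(*np.diff(np.vstack([pts, pts[:1]]), axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(ds)])[:-1]
    tgt = np.interp(np.linspace(0, s[-1] + ds[-1], n, endpoint=False), s, th)
    ring = np.column_stack([a * np.cos(tgt), b * np.sin(tgt)])
    nrm = np.column_stack([np.cos(tgt) / a, np.sin(tgt) / b])
    nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
    return ring, nrm


def _hex_grid(bounds: tuple[float, float, float, float], h: float) -> np.ndarray:
    x0, y0, x1, y1 = bounds
    dy = h * np.sqrt(3) / 2
    rows = []
    y = y0
    row = 0
    while y <= y1:
        xs = np.arange(x0 + (h / 2 if row % 2 else 0.0), x1 + 1e-12, h)
        rows.append(np.column_stack([xs, np.full_like(xs, y)]))
        y += dy
        row += 1
    return np.concatenate(rows) if rows else np.empty((0, 2))


def generate_mesh(
    geometry: TumorGeometry,
    controls: MeshControls | None = None,
    **overrides,
) -> SimMesh:
    """Generate the boundary-layer mesh for a tumor geometry.

    ``overrides`` set individual :class:`MeshControls` fields. The surface
    band is shrunk automatically (and logged) if the vessel network leaves
    too little clearance for the configured band width.
    """
    c = controls or MeshControls()
    for k, v in overrides.items():
        if not hasattr(c, k):
            raise TypeError(f"unknown mesh control {k!r}")
        setattr(c, k, v)

    a, b = geometry.semi_axes
    network = geometry.network
    has_vessels = bool(network.polygons)
    w = network.estimate_channel_width() if has_vessels else 0.0
    h_wall = c.h_wall or (w / 4.0 if w else c.h_interior)
    h_lumen = c.h_lumen or (w / 4.0 if w else c.h_interior)

    # --- structured boundary-layer band at the tumor surface -------------
    band = c.surface_band_frac * min(a, b)
    clearance = geometry.boundary_clearance()
    if band > 0.7 * clearance:
        band = 0.7 * clearance
        logger.info("surface boundary-layer band shrunk to %.4g mm for lumen clearance", band)
    depths = np.concatenate([[0.0], np.cumsum(layer_thicknesses(band, c.n_bl_layers, c.bl_growth))])
    perimeter = float(geometry.ellipse.exterior.length)
    n_surf = max(int(round(perimeter / min(c.h_interior, h_wall * 4))), 64)
    ring0, nrm = _ellipse_ring(a, b, n_surf)
    rings = np.stack([ring0 - d * nrm for d in depths])  # (L+1, n_surf, 2)

    nodes = [rings.reshape(-1, 2)]
    n_ring_nodes = (c.n_bl_layers + 1) * n_surf

    band_tris = []
    for i in range(c.n_bl_layers):
        o = i * n_surf + np.arange(n_surf)
        nx = i * n_surf + (np.arange(n_surf) + 1) % n_surf
        ii = o + n_surf
        inx = nx + n_surf
        band_tris.append(np.column_stack([o, nx, inx]))
        band_tris.append(np.column_stack([o, inx, ii]))
    band_tris = np.concatenate(band_tris)

    ring_inner = rings[-1]
    inner_poly = Polygon(ring_inner)
    idx0 = n_ring_nodes  # Delaunay points start here; ring_inner reused by index

    # --- graded point sets for the free-triangle region ------------------
    free_pts = [ring_inner]

    lumen_union = network.union() if has_vessels else None
    wall_rings_meta = []
    if has_vessels:
        lumen_boundary = unary_union([orient(p).exterior for p in network.polygons])
        for poly in network.polygons:
            coords = np.asarray(orient(poly).exterior.coords)[:-1]
            wall = _resample_closed(coords, h_wall)
            free_pts.append(wall)
            normals = _closed_normals(wall)
            gaps = layer_thicknesses(
                max(c.wall_band_factor * w, 1.6 * h_wall * 0.4), c.n_wall_layers, c.bl_growth
            )
            gaps = np.maximum(gaps, 0.35 * h_wall)  # keep point-cloud anisotropy bounded
            d = 0.0
            for g in gaps:
                d += g
                ring = wall + d * normals
                dist = shapely.distance(lumen_boundary, shapely.points(ring))
                keep = (
                    (dist >= 0.7 * d)
                    & ~shapely.contains_xy(lumen_union, ring[:, 0], ring[:, 1])
                    & shapely.contains_xy(inner_poly, ring[:, 0], ring[:, 1])
                )
                wall_rings_meta.append((ring[keep], 0.42 * g))
            # lumen interior fill
            grid = _hex_grid(poly.bounds, h_lumen)
            inside = shapely.contains_xy(poly, grid[:, 0], grid[:, 1])
            dist = shapely.distance(lumen_boundary, shapely.points(grid))
            grid = grid[inside & (dist >= 0.5 * h_lumen)]
            wall_rings_meta.append((grid, 0.45 * h_lumen))

    # interior tissue grid
    grid = _hex_grid((-a, -b, a, b), c.h_interior)
    keep = shapely.contains_xy(inner_poly, grid[:, 0], grid[:, 1])
    # stay off the inner ring itself
    ring_tree = cKDTree(ring_inner)
    keep &= ring_tree.query(grid)[0] >= 0.55 * c.h_interior
    if has_vessels:
        keep &= ~shapely.contains_xy(lumen_union, grid[:, 0], grid[:, 1])
    wall_rings_meta.append((grid[keep], 0.55 * c.h_interior))

    # progressive proximity pruning: earlier (finer/fixed) points win
    for pts, radius in wall_rings_meta:
        if len(pts) == 0:
            continue
        tree = cKDTree(np.concatenate(free_pts))
        d, _ = tree.query(pts)
        sel = d >= radius
        pts = pts[sel]
        if len(pts):
            # thin mutual collisions inside the batch
            keep_mask = np.ones(len(pts), dtype=bool)
            btree = cKDTree(pts)
            pairs = btree.query_pairs(radius, output_type="ndarray")
            for i, j in pairs:
                if keep_mask[i] and keep_mask[j]:
                    keep_mask[j] = False
            pts = pts[keep_mask]
        free_pts.append(pts)

    del_pts = np.concatenate(free_pts)
    tri = Delaunay(del_pts)
    # Delaunay point i -> global node index: the first n_surf points are the
    # shared inner-ring nodes already stored in the structured-band block.
    remap = np.empty(len(del_pts), dtype=int)
    remap[:n_surf] = c.n_bl_layers * n_surf + np.arange(n_surf)
    remap[n_surf:] = idx0 + np.arange(len(del_pts) - n_surf)
    del_tris = remap[tri.simplices]

    nodes.append(del_pts[n_surf:])  # inner-ring points already stored in band block
    all_nodes = np.concatenate(nodes)
    # compact away the unused duplicate slots
    used = np.zeros(len(all_nodes), dtype=bool)
    tris = np.concatenate([band_tris, del_tris])
    used[tris] = True
    new_index = -np.ones(len(all_nodes), dtype=int)
    new_index[used] = np.arange(used.sum())
    all_nodes = all_nodes[used]
    tris = new_index[tris]

    # orient CCW
    p = all_nodes[tris]
    u, v = p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]
    area2 = u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]
    flip = area2 < 0
    tris[flip] = tris[flip][:, [0, 2, 1]]
    degenerate = np.abs(area2) < 1e-14
    tris = tris[~degenerate]

    is_layer = np.zeros(len(tris), dtype=bool)
    is_layer[: len(band_tris)] = True

    # region classification
    cen = all_nodes[tris].mean(axis=1)
    region = np.zeros(len(tris), dtype=int)
    if has_vessels:
        region[shapely.contains_xy(lumen_union, cen[:, 0], cen[:, 1])] = LUMEN

    mesh = _tag_boundaries(all_nodes, tris, region, is_layer, geometry, w, h_wall)
    mesh.validate()
    if mesh.min_angle_deg(free_only=True) < c.quality_floor_deg:
        raise MeshFailureError(
            f"mesh-failure: free-triangle min angle "
            f"{mesh.min_angle_deg():.2f} deg below floor {c.quality_floor_deg}"
        )
    return mesh


def _point_segment_distance(p: np.ndarray, s0: np.ndarray, s1: np.ndarray) -> np.ndarray:
    d = s1 - s0
    L2 = (d * d).sum()
    if L2 == 0:
        return np.linalg.norm(p - s0, axis=1)
    t = np.clip(((p - s0) @ d) / L2, 0.0, 1.0)
    proj = s0 + t[:, None] * d
    return np.linalg.norm(p - proj, axis=1)


def _tag_boundaries(nodes, tris, region, is_layer, geometry, w, h_wall) -> SimMesh:
    """Extract exterior + tissue/lumen interface edges and tag them."""
    edges = np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    owner = np.tile(np.arange(len(tris)), 3)
    key = np.sort(edges, axis=1)
    order = np.lexsort((key[:, 1], key[:, 0]))
    key, edges, owner = key[order], edges[order], owner[order]
    same = np.all(key[1:] == key[:-1], axis=1)
    # exterior edges appear once
    first = np.concatenate([[True], ~same])
    count = np.add.reduceat(np.ones(len(key)), np.flatnonzero(first))
    starts = np.flatnonzero(first)

    b_edges, b_tags = [], []
    iface_edges = []
    for s, cnt in zip(starts, count):
        if cnt == 1:
            b_edges.append(edges[s])
            b_tags.append("tumor_surface")
        elif cnt == 2 and region[owner[s]] != region[owner[s + 1]]:
            iface_edges.append(edges[s])

    terminals = geometry.network.terminals
    roles = {t.label: t.role for t in terminals}
    if iface_edges:
        iface_edges = np.asarray(iface_edges)
        mids = nodes[iface_edges].mean(axis=1)
        tag = np.full(len(iface_edges), "vessel_wall", dtype=object)
        tol = max(0.35 * (w or h_wall), 0.5 * h_wall)
        for t in terminals:
            dist = _point_segment_distance(mids, t.segment[0], t.segment[1])
            hit = dist < tol
            if not hit.any():
                hit = dist == dist.min()  # guarantee each terminal at least one facet
            tag[hit] = t.label
        b_edges.extend(iface_edges)
        b_tags.extend(tag.tolist())

    return SimMesh(
        nodes=nodes,
        triangles=tris,
        region=region,
        boundary_edges=np.asarray(b_edges, dtype=int),
        boundary_tags=np.asarray(b_tags, dtype=object),
        is_layer=is_layer,
        terminal_roles=roles,
        geometry=geometry,
    )


def rectangle_channel_mesh(
    length: float,
    width: float,
    h: float,
    region: int = LUMEN,
    left_tag: str = "Inlet1",
    right_tag: str = "Outlet1",
    side_tag: str = "vessel_wall",
    terminal_roles: dict[str, str] | None = None,
) -> SimMesh:
    """Structured mesh of an axis-aligned rectangle [0,L]x[0,W] (mm).

    A plain fixture for channel-flow (plane Poiseuille) and 1D-strip
    transport verification; left/right/side boundary tags are configurable.
    """
    nx = max(int(round(length / h)), 2) + 1
    ny = max(int(round(width / h)), 2) + 1
    xs = np.linspace(0, length, nx)
    ys = np.linspace(0, width, ny)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel()])
    idx = np.arange(nx * ny).reshape(nx, ny)
    tris = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            n00, n01, n10, n11 = idx[i, j], idx[i, j + 1], idx[i + 1, j], idx[i + 1, j + 1]
            if (i + j) % 2 == 0:
                tris += [[n00, n10, n11], [n00, n11, n01]]
            else:
                tris += [[n00, n10, n01], [n10, n11, n01]]
    tris = np.asarray(tris)
    b_edges, b_tags = [], []
    for j in range(ny - 1):
        b_edges.append([idx[0, j], idx[0, j + 1]])
        b_tags.append(left_tag)
        b_edges.append([idx[-1, j], idx[-1, j + 1]])
        b_tags.append(right_tag)
    for i in range(nx - 1):
        b_edges.append([idx[i, 0], idx[i + 1, 0]])
        b_tags.append(side_tag)
        b_edges.append([idx[i, -1], idx[i + 1, -1]])
        b_tags.append(side_tag)
    if terminal_roles is None:
        terminal_roles = {left_tag: "inlet", right_tag: "outlet"}
    return SimMesh(
        nodes=nodes,
        triangles=tris,
        region=np.full(len(tris), region),
        boundary_edges=np.asarray(b_edges),
        boundary_tags=np.asarray(b_tags, dtype=object),
        is_layer=np.zeros(len(tris), dtype=bool),
        terminal_roles=terminal_roles,
        geometry=None,
    )
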