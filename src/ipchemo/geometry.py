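"""Tumor domain assembly: ellipse plus embedded vessel lumens.

The nodule is idealized as an ellipse (default semi-axes 2.425 mm and
1.755 mm, i.e. full axis lengths 4.85 mm x 3.51 mm) containing the vessel
network strictly in its interior. The boundary of the simulation domain is
partitioned into the tumor surface, the vessel walls, and the named
inlet/outlet terminal openings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Point, Polygon
from shapely.ops import unary_union

from .errors import GeometryClashError
from .imaging import VesselNetwork

__all__ = ["TumorGeometry", "build_tumor_geometry", "DEFAULT_SEMI_AXES"]

#: semi-axes (mm) matching the printed full axis lengths 4.85 mm / 3.51 mm
DEFAULT_SEMI_AXES = (2.425, 1.755)


def _ellipse_polygon(a: float, b: float, n: int = 256) -> Polygon:
    return shapely.affinity.scale(Point(0.0, 0.0).buffer(1.0, quad_segs=n // 4), a, b)


@dataclass
class TumorGeometry:
    """Elliptical tumor domain with tagged vessel lumens (mm units)."""

    semi_axis_long: float
    semi_axis_short: float
    network: VesselNetwork
    ellipse: Polygon = field(repr=False, default=None)

    def __post_init__(self):
        if self.ellipse is None:
            self.ellipse = _ellipse_polygon(self.semi_axis_long, self.semi_axis_short)

    @property
    def semi_axes(self) -> tuple[float, float]:
        return (self.semi_axis_long, self.semi_axis_short)

    @property
    def ellipse_area(self) -> float:
        """Exact ellipse area pi*a*b (mm^2)."""
        return float(np.pi * self.semi_axis_long * self.semi_axis_short)

    @property
    def lumen_area(self) -> float:
        return self.network.total_area

    @property
    def tissue_area(self) -> float:
        """Tissue area = ellipse area minus lumen area (mm^2)."""
        return self.ellipse_area - self.lumen_area

    @property
    def terminal_tags(self) -> list[str]:
        return [t.label for t in self.network.terminals]

    @property
    def boundary_tags(self) -> list[str]:
        tags = ["tumor_surface"]
        if self.network.polygons:
            tags.append("vessel_wall")
        tags.extend(self.terminal_tags)
        return tags

    def boundary_clearance(self) -> float:
        """Minimum distance (mm) from any lumen to the tumor surface."""
        if not self.network.polygons:
            return min(self.semi_axes)
        lumen = self.network.union()
        return float(self.ellipse.exterior.distance(lumen))


def build_tumor_geometry(
    network: VesselNetwork,
    axes: tuple[float, float] = DEFAULT_SEMI_AXES,
    scale_to_fit: bool = False,
    fit_margin: float = 0.12,
) -> TumorGeometry:
    """Assemble the tagged tumor geometry from a vessel network.

    ``axes`` are the ellipse semi-axes in mm. Lumens must lie strictly
    inside the ellipse; with ``scale_to_fit`` the whole network is scaled
    uniformly about the origin until its furthest point sits at
    ``(1 - fit_margin)`` of the boundary radius, otherwise a crossing
    lumen raises a ``geometry-clash`` error.
    """
    a, b = axes
    ellipse = _ellipse_polygon(a, b)
    if network.polygons:
        lumen = network.union()
        if not lumen.within(ellipse):
            if not scale_to_fit:
                raise GeometryClashError(
                    "geometry-clash: vessel lumen crosses the tumor surface"
                )
            pts = np.concatenate(
                [np.asarray(p.exterior.coords) for p in network.polygons]
            )
            rmax = float(np.hypot(pts[:, 0] / a, pts[:, 1] / b).max())
            s = (1.0 - fit_margin) / rmax
            network = VesselNetwork(
                polygons=[shapely.affinity.scale(p, s, s, origin=(0, 0)) for p in network.polygons],
                terminals=[
                    type(t)(segment=t.segment * s, role=t.role, label=t.label)
                    for t in network.terminals
                ],
                channel_width=(network.channel_width or 0) * s or None,
            )
            if not network.union().within(ellipse):
                raise GeometryClashError("geometry-clash: network cannot be scaled to fit")
    return TumorGeometry(semi_axis_long=a, semi_axis_short=b, network=network, ellipse=ellipse)
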