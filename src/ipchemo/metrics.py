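"""Treatment-efficacy and penetration metrics.

* FK, fraction of killed cells: FK = 1 - exp(-omega * C_I) with the
  Doxorubicin survival constant omega (m^3/mol).
* AUC: time integral of the spatial-mean free-drug concentration
  (mol m^-3 s) — the drug-availability measure.
* W_1/2, half-width: depth from the tumor surface at which the free drug
  falls to half the exterior bath concentration — the penetration measure,
  evaluated from both ends of each sampling axis.
* Axis profiles: fields sampled along four lines through the tumor
  (default 0/45/90/135 degrees through the centroid).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from matplotlib.tri import LinearTriInterpolator, Triangulation

from .errors import AxisOutsideError, BadSeriesError, InvalidConcentrationError
from .geometry import TumorGeometry
from .meshing import TISSUE, SimMesh

__all__ = [
    "OMEGA_DOXORUBICIN",
    "AxisSpec",
    "EfficacyReport",
    "fraction_killed",
    "auc_mean_free",
    "half_width",
    "axis_profiles",
    "half_widths",
]

#: Doxorubicin cell-survival constant omega (m^3/mol)
OMEGA_DOXORUBICIN = 0.6603


@dataclass
class AxisSpec:
    """Sampling axes: lines through ``anchor`` at the given angles (deg)."""

    angles_deg: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    anchor: tuple[float, float] = (0.0, 0.0)

    @property
    def labels(self) -> list[str]:
        return [f"Axis{i + 1}" for i in range(len(self.angles_deg))]

    def segments(self, geometry: TumorGeometry) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Chord endpoints on the tumor surface for each axis.

        Solves the line/ellipse intersection; an axis whose anchor lies
        outside the ellipse raises an ``axis-outside`` error.
        """
        a, b = geometry.semi_axes
        x0, y0 = self.anchor
        if (x0 / a) ** 2 + (y0 / b) ** 2 >= 1.0:
            raise AxisOutsideError("axis-outside: anchor not inside the tumor")
        out = {}
        for label, ang in zip(self.labels, self.angles_deg):
            d = np.array([np.cos(np.deg2rad(ang)), np.sin(np.deg2rad(ang))])
            # ((x0 + t dx)/a)^2 + ((y0 + t dy)/b)^2 = 1
            A = (d[0] / a) ** 2 + (d[1] / b) ** 2
            B = 2 * (x0 * d[0] / a**2 + y0 * d[1] / b**2)
            C = (x0 / a) ** 2 + (y0 / b) ** 2 - 1.0
            disc = B * B - 4 * A * C
            t1 = (-B - np.sqrt(disc)) / (2 * A)
            t2 = (-B + np.sqrt(disc)) / (2 * A)
            p1 = np.array([x0, y0]) + t1 * d
            p2 = np.array([x0, y0]) + t2 * d
            out[label] = (p1, p2)
        return out


def fraction_killed(
    C_I: np.ndarray | float,
    omega: float = OMEGA_DOXORUBICIN,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray | float, float]:
    """Pharmacodynamic kill fraction FK = 1 - exp(-omega C_I).

    Returns the elementwise field and its (area-weighted, if ``weights``
    given) mean. Negative concentrations are rejected.
    """
    C = np.asarray(C_I, dtype=float)
    if np.any(C < 0):
        raise InvalidConcentrationError("invalid-concentration: negative C_I")
    if omega <= 0:
        raise ValueError("omega must be positive")
    fk = 1.0 - np.exp(-omega * C)
    if weights is not None:
        mean = float((fk * weights).sum() / weights.sum())
    else:
        mean = float(np.mean(fk))
    if C.ndim == 0:
        return float(fk), mean
    return fk, mean


def auc_mean_free(t: np.ndarray, mean_C_F: np.ndarray) -> float:
    """Trapezoidal AUC of the mean free-drug series (mol m^-3 s)."""
    t = np.asarray(t, dtype=float)
    v = np.asarray(mean_C_F, dtype=float)
    if len(t) < 2 or len(t) != len(v):
        raise BadSeriesError("bad-series: need >= 2 aligned samples")
    if np.any(np.diff(t) <= 0):
        raise BadSeriesError("bad-series: time not strictly increasing")
    return float(np.trapezoid(v, t))


def half_width(
    depth: np.ndarray, C_F: np.ndarray, C_exterior: float
) -> float | None:
    """First depth (mm) where C_F crosses C_exterior/2 from above.

    The profile must start at the surface (depth 0) and run inward.
    Returns None (the "no-crossing" signal) when the profile never reaches
    the half level from above — e.g. a uniform profile at the exterior
    concentration, or one starting below the half level.
    """
    if C_exterior <= 0:
        raise ValueError("C_exterior must be positive")
    half = C_exterior / 2.0
    d = np.asarray(depth, dtype=float)
    v = np.asarray(C_F, dtype=float)
    ok = np.isfinite(v)
    d, v = d[ok], v[ok]
    if len(v) < 2 or v[0] < half:
        return None
    below = v < half
    if not below.any():
        return None
    i = int(np.argmax(below))  # first sample strictly below the half level
    if i == 0:
        return None
    frac = (v[i - 1] - half) / (v[i - 1] - v[i])
    return float(d[i - 1] + frac * (d[i] - d[i - 1]))


def axis_profiles(
    mesh: SimMesh,
    field: np.ndarray,
    axes: AxisSpec | None = None,
    n_samples: int = 400,
    geometry: TumorGeometry | None = None,
) -> dict[str, pd.DataFrame]:
    """Sample a nodal field along the analysis axes.

    Interpolation is linear over the tissue triangulation; samples falling
    inside a lumen (or outside the domain) are flagged ``in_lumen`` and
    carry NaN values.
    """
    axes = axes or AxisSpec()
    geometry = geometry or mesh.geometry
    if geometry is None:
        raise AxisOutsideError("axis-outside: mesh carries no geometry to clip against")
    tissue_tris = mesh.triangles[mesh.region == TISSUE]
    tri = Triangulation(mesh.nodes[:, 0], mesh.nodes[:, 1], tissue_tris)
    interp = LinearTriInterpolator(tri, np.where(np.isfinite(field), field, 0.0))
    out = {}
    for label, (p1, p2) in axes.segments(geometry).items():
        s = np.linspace(0.0, 1.0, n_samples)
        pts = p1[None, :] + s[:, None] * (p2 - p1)[None, :]
        vals = interp(pts[:, 0], pts[:, 1])
        flagged = np.ma.getmaskarray(vals)
        arc = s * np.linalg.norm(p2 - p1)
        out[label] = pd.DataFrame(
            {
                "s": arc,
                "x": pts[:, 0],
                "y": pts[:, 1],
                "value": np.ma.filled(vals, np.nan),
                "in_lumen": flagged,
            }
        )
    return out


def half_widths(
    profiles: dict[str, pd.DataFrame], C_exterior: float
) -> dict[str, float | None]:
    """W_1/2 from both ends of each axis profile (up to 2 per axis).

    Keys are ``"<axis>:start"`` / ``"<axis>:end"``; values are depths in
    mm or None where the half level is never crossed.
    """
    out: dict[str, float | None] = {}
    for label, df in profiles.items():
        s = df["s"].to_numpy()
        v = df["value"].to_numpy()
        out[f"{label}:start"] = half_width(s, v, C_exterior)
        out[f"{label}:end"] = half_width(s[-1] - s[::-1], v[::-1], C_exterior)
    return out


@dataclass
class EfficacyReport:
    """Aggregate treatment-efficacy metrics for one run."""

    AUC: float                                  # mol m^-3 s
    W_half_mm: dict[str, float | None]          # per axis end
    FK_mean: float
    FK_max: float
    mean_series: pd.DataFrame = field(repr=False)
    flow_summary: dict = field(default_factory=dict)

    @property
    def W_half_min(self) -> float | None:
        vals = [v for v in self.W_half_mm.values() if v is not None]
        return min(vals) if vals else None

    @property
    def W_half_max(self) -> float | None:
        vals = [v for v in self.W_half_mm.values() if v is not None]
        return max(vals) if vals else None

    def to_dict(self) -> dict:
        return {
            "AUC_mol_m3_s": self.AUC,
            "W_half_mm": self.W_half_mm,
            "W_half_min_mm": self.W_half_min,
            "W_half_max_mm": self.W_half_max,
            "FK_mean": self.FK_mean,
            "FK_max": self.FK_max,
            "flow_summary": self.flow_summary,
        }
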