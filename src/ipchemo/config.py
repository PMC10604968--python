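"""Run configuration: parsing, unit normalization and validation.

Configs are YAML with an optional per-entry ``{value, units}`` form, e.g.

.. code-block:: yaml

    drug:
      D_F: {value: 3.40e-6, units: cm^2/s}   # -> 3.40e-10 m^2/s
    bcs:
      inlet_pressure: {value: 25, units: mmHg}

Everything is normalized to SI at parse time (lengths that describe the
geometry and mesh stay in mm, the package's geometry unit); range errors
are reported per field.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .flow import FlowBCs, TissueParams
from .meshing import MeshControls
from .metrics import OMEGA_DOXORUBICIN
from .transport import DrugParams
from .units import to_si

__all__ = ["RunConfig", "load_config", "validate_config", "default_config", "config_hash"]


def _scalar(raw, field_name: str, to_mm: bool = False) -> float:
    """Unwrap a scalar or {value, units} entry to SI (or mm)."""
    try:
        if isinstance(raw, dict):
            v = to_si(float(raw["value"]), raw.get("units"))
            if to_mm and raw.get("units") is not None:
                v *= 1e3  # SI metres back to the geometry unit
            return v
        return float(raw)
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"config-error: field {field_name!r}: {exc}") from exc


@dataclass
class RunConfig:
    """Fully normalized pipeline configuration."""

    seed: int = 0
    coupling_mode: str = "wall_coupled"
    network: dict = field(default_factory=lambda: {
        "kind": "synthetic",
        "n_inlets": 5,
        "n_outlets": 6,
        "channel_width_mm": 0.05,
    })
    semi_axes_mm: tuple[float, float] = (2.425, 1.755)
    tissue: TissueParams = field(default_factory=TissueParams)
    drug: DrugParams = field(default_factory=DrugParams)
    bcs: FlowBCs = field(default_factory=FlowBCs)
    mesh: MeshControls = field(default_factory=MeshControls)
    duration: float = 3600.0
    dt: float = 1.0
    checkpoints: tuple[float, ...] | None = None
    omega: float = OMEGA_DOXORUBICIN
    axes_deg: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    legacy_unbinding_sign: bool = False
    outdir: str = "out"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tissue"] = asdict(self.tissue)
        d["drug"] = asdict(self.drug)
        d["bcs"] = asdict(self.bcs)
        d["mesh"] = asdict(self.mesh)
        return d


# fields taking {value, units} entries, grouped by dataclass section
_SECTION_FIELDS = {
    "tissue": ["K", "L_p", "S_over_V", "P_B", "pi_B", "pi_i", "sigma_s", "phi_L", "mu"],
    "drug": [
        "D_F", "P_wall", "K_ON", "K_OFF", "K_INT", "C_rec",
        "phi", "sigma_f", "C_P", "C_surface",
    ],
    "bcs": ["inlet_pressure", "outlet_pressure", "surface_pressure"],
}

_MESH_FIELDS = [
    "h_interior", "n_bl_layers", "bl_growth", "surface_band_frac",
    "n_wall_layers", "wall_band_factor", "h_wall", "h_lumen", "quality_floor_deg",
]


def validate_config(raw: dict | None) -> RunConfig:
    """Normalize a raw config mapping into a :class:`RunConfig`.

    Unknown keys raise; physically out-of-range values raise with the
    offending field named.
    """
    raw = dict(raw or {})
    cfg = RunConfig()

    sections = {}
    for sec, names in _SECTION_FIELDS.items():
        block = raw.pop(sec, {}) or {}
        unknown = set(block) - set(names)
        if unknown:
            raise ConfigError(f"config-error: unknown {sec} field(s): {sorted(unknown)}")
        kwargs = {k: _scalar(v, f"{sec}.{k}") for k, v in block.items()}
        cls = {"tissue": TissueParams, "drug": DrugParams, "bcs": FlowBCs}[sec]
        try:
            sections[sec] = cls(**kwargs)
        except ValueError as exc:
            raise ConfigError(f"config-error: {sec}: {exc}") from exc
    cfg.tissue, cfg.drug, cfg.bcs = sections["tissue"], sections["drug"], sections["bcs"]

    mesh_block = raw.pop("mesh", {}) or {}
    unknown = set(mesh_block) - set(_MESH_FIELDS)
    if unknown:
        raise ConfigError(f"config-error: unknown mesh field(s): {sorted(unknown)}")
    mesh_kwargs = {}
    for k, v in mesh_block.items():
        if k in ("n_bl_layers", "n_wall_layers"):
            mesh_kwargs[k] = int(v)
        elif k in ("h_interior", "h_wall", "h_lumen") and v is not None:
            mesh_kwargs[k] = _scalar(v, f"mesh.{k}", to_mm=True)
        else:
            mesh_kwargs[k] = float(v)
    cfg.mesh = MeshControls(**mesh_kwargs)
    if cfg.mesh.n_bl_layers < 1 or cfg.mesh.bl_growth <= 0:
        raise ConfigError("config-error: mesh boundary-layer controls out of range")

    geom = raw.pop("geometry", {}) or {}
    if "semi_axes_mm" in geom:
        ax = geom["semi_axes_mm"]
        cfg.semi_axes_mm = (float(ax[0]), float(ax[1]))
    elif "axis_lengths_mm" in geom:
        ax = geom["axis_lengths_mm"]  # printed full-axis lengths
        cfg.semi_axes_mm = (float(ax[0]) / 2.0, float(ax[1]) / 2.0)
    if not all(a > 0 for a in cfg.semi_axes_mm):
        raise ConfigError("config-error: geometry semi-axes must be positive")

    if "network" in raw:
        cfg.network = dict(raw.pop("network"))
        cfg.network.setdefault("kind", "synthetic")
    time_block = raw.pop("time", {}) or {}
    cfg.duration = _scalar(time_block.get("duration", cfg.duration), "time.duration")
    cfg.dt = _scalar(time_block.get("dt", cfg.dt), "time.dt")
    if "checkpoints" in time_block and time_block["checkpoints"] is not None:
        cfg.checkpoints = tuple(float(c) for c in time_block["checkpoints"])
    if cfg.duration < 0 or cfg.dt <= 0:
        raise ConfigError("config-error: need duration >= 0 and dt > 0")

    met = raw.pop("metrics", {}) or {}
    cfg.omega = _scalar(met.get("omega", cfg.omega), "metrics.omega")
    if cfg.omega <= 0:
        raise ConfigError("config-error: metrics.omega must be positive")
    if "axes_deg" in met:
        cfg.axes_deg = tuple(float(a) for a in met["axes_deg"])

    cfg.seed = int(raw.pop("seed", cfg.seed))
    cfg.coupling_mode = str(raw.pop("coupling_mode", cfg.coupling_mode))
    if cfg.coupling_mode not in ("distributed", "wall_coupled"):
        raise ConfigError(f"config-error: unknown coupling_mode {cfg.coupling_mode!r}")
    cfg.legacy_unbinding_sign = bool(raw.pop("legacy_unbinding_sign", False))
    cfg.outdir = str(raw.pop("output", cfg.outdir))
    if raw:
        raise ConfigError(f"config-error: unknown top-level key(s): {sorted(raw)}")
    return cfg


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh))


def default_config() -> RunConfig:
    return validate_config({})


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
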