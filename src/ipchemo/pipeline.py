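"""End-to-end orchestration: image/network -> mesh -> flow -> transport -> metrics.

One call runs the whole simulation the way the solution strategy is
staged: the steady intravascular and interstitial flow fields are solved
first, then frozen as input to the transient drug-transport phase, and the
efficacy metrics are evaluated on the result. All artifacts (fields,
series, report, manifest) are written under the configured output
directory; reruns with an identical config reproduce them bit-identically.
"""

from __future__ import annotations

import logging
import platform
from pathlib import Path

import numpy as np

from . import __version__, imaging, io, metrics
from .config import RunConfig, config_hash
from .errors import ConfigError
from .flow import flow_summary, solve_interstitial
from .geometry import build_tumor_geometry
from .meshing import generate_mesh
from .metrics import AxisSpec, EfficacyReport, auc_mean_free, fraction_killed
from .transport import run_transport

logger = logging.getLogger(__name__)

__all__ = ["build_network", "run_pipeline"]


def build_network(cfg: RunConfig) -> imaging.VesselNetwork:
    """Materialize the vessel network described by the config."""
    spec = cfg.network
    kind = spec.get("kind", "synthetic")
    if kind == "none":
        return imaging.VesselNetwork(polygons=[])
    if kind == "synthetic":
        return imaging.generate_synthetic_network(
            n_inlets=int(spec.get("n_inlets", 5)),
            n_outlets=int(spec.get("n_outlets", 6)),
            semi_axes=cfg.semi_axes_mm,
            channel_width=float(spec.get("channel_width_mm", 0.05)),
            seed=int(spec.get("seed", cfg.seed)),
        )
    if kind == "image":
        import imageio.v3 as iio

        pixel_size = float(spec["pixel_size_mm"])
        img = imaging.RasterImage(
            pixels=iio.imread(spec["path"]),
            pixel_size=pixel_size,
            origin=tuple(spec.get("origin_mm", (0.0, 0.0))),
        )
        mask = imaging.equalize_and_binarize(
            img, threshold_policy=spec.get("threshold_policy", "otsu")
        )
        net = imaging.extract_vessel_network(
            mask,
            pixel_size,
            min_area=float(spec.get("min_area_mm2", 0.0)),
            origin=img.origin,
        )
        terms = spec.get("terminals", [])
        if terms:
            net = imaging.assign_terminals(
                net,
                points=[t["point_mm"] for t in terms],
                roles=[t["role"] for t in terms],
                labels=[t.get("label") for t in terms] if all("label" in t for t in terms) else None,
            )
        return net
    if kind == "file":
        return imaging.read_network(spec["path"])
    raise ConfigError(f"config-error: unknown network kind {kind!r}")


def run_pipeline(
    cfg: RunConfig, write_artifacts: bool = True, make_plots: bool = True
) -> tuple[EfficacyReport, dict]:
    """Execute all stages and return the efficacy report plus artifact paths."""
    network = build_network(cfg)
    geometry = build_tumor_geometry(
        network, axes=cfg.semi_axes_mm, scale_to_fit=cfg.network.get("scale_to_fit", False)
    )
    mesh = generate_mesh(geometry, controls=cfg.mesh)
    logger.info("mesh: %d nodes, %d triangles", mesh.n_nodes, mesh.n_triangles)

    flow = solve_interstitial(
        mesh, cfg.tissue, cfg.bcs, coupling_mode=cfg.coupling_mode
    )
    fsum = flow_summary(flow)

    states, series, solver = run_transport(
        mesh,
        flow,
        cfg.drug,
        duration=cfg.duration,
        dt=cfg.dt,
        checkpoints=cfg.checkpoints,
        legacy_unbinding_sign=cfg.legacy_unbinding_sign,
    )
    final = states[-1]

    axes = AxisSpec(angles_deg=cfg.axes_deg)
    profiles = metrics.axis_profiles(mesh, final.C_F, axes, geometry=geometry)
    whalf = metrics.half_widths(profiles, cfg.drug.C_surface)
    auc = (
        auc_mean_free(series["t"].to_numpy(), series["C_F"].to_numpy())
        if len(series) > 1
        else 0.0
    )
    fk_field, fk_mean = fraction_killed(final.C_I, cfg.omega, weights=solver.m_diag)
    report = EfficacyReport(
        AUC=auc,
        W_half_mm=whalf,
        FK_mean=fk_mean,
        FK_max=float(np.max(fk_field)),
        mean_series=series,
        flow_summary=fsum,
    )

    artifacts: dict[str, str] = {}
    if write_artifacts:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        imaging.write_network(network, out / "network.json")
        io.write_json(out / "report.json", report.to_dict())
        series.to_csv(out / "mean_series.csv", index=False)
        point_data = {
            "IFP": flow.IFP,
            "C_F": final.C_F,
            "C_B": final.C_B,
            "C_I": final.C_I,
            "C_T": final.C_T,
            "FK": np.where(np.isfinite(fk_field), fk_field, 0.0),
        }
        if flow.IBP is not None:
            point_data["IBP"] = flow.IBP
        cell_data = {"IFV": flow.IFV, "region": mesh.region.astype(float)}
        if flow.IBV is not None:
            cell_data["IBV"] = flow.IBV
        io.write_vtk(out / "fields.vtk", mesh, point_data, cell_data)
        for label, df in profiles.items():
            df.to_csv(out / f"profile_{label}.csv", index=False)
        manifest = {
            "package": "ipchemo",
            "version": __version__,
            "config": cfg.to_dict(),
            "config_hash": config_hash(cfg),
            "seed": cfg.seed,
            "python": platform.python_version(),
            "mesh_nodes": mesh.n_nodes,
            "mesh_triangles": mesh.n_triangles,
            "mass_budget_max_rel_violation": solver.max_budget_violation(),
        }
        io.write_json(out / "manifest.json", manifest)
        if make_plots:
            io.plot_mean_series(series, out / "mean_series.png")
            io.plot_profiles(profiles, out / "profiles_C_F.png", ylabel="C_F (mol/m^3)")
            fk_t = 1.0 - np.exp(-cfg.omega * series["C_I"].to_numpy())
            io.plot_fk_series(series["t"].to_numpy(), fk_t, out / "fk_series.png")
        artifacts = {p.name: str(p) for p in sorted(out.iterdir())}
    return report, artifacts
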