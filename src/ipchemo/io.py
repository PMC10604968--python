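"""Field export (legacy VTK ASCII), CSV/JSON artifacts and plots."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .meshing import SimMesh


def write_vtk(
    path,
    mesh: SimMesh,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
) -> None:
    """Write the mesh and fields as a legacy ASCII VTK unstructured grid."""
    path = Path(path)
    lines = [
        "# vtk DataFile Version 3.0",
        "ipchemo fields",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    for x, y in mesh.nodes:
        lines.append(f"{x:.10g} {y:.10g} 0")
    lines.append(f"CELLS {mesh.n_triangles} {4 * mesh.n_triangles}")
    for t in mesh.triangles:
        lines.append(f"3 {t[0]} {t[1]} {t[2]}")
    lines.append(f"CELL_TYPES {mesh.n_triangles}")
    lines.extend(["5"] * mesh.n_triangles)

    def _emit(tag_count: str, data: dict[str, np.ndarray]):
        lines.append(tag_count)
        for name, arr in data.items():
            arr = np.asarray(arr, dtype=float)
            arr = np.where(np.isfinite(arr), arr, 0.0)
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(f"{v:.10g}" for v in arr)
            else:
                lines.append(f"VECTORS {name} double")
                lines.extend(f"{v[0]:.10g} {v[1]:.10g} 0" for v in arr)

    if point_data:
        _emit(f"POINT_DATA {mesh.n_nodes}", point_data)
    if cell_data:
        _emit(f"CELL_DATA {mesh.n_triangles}", cell_data)
    path.write_text("\n".join(lines) + "\n")


def write_json(path, obj) -> None:
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o).__name__)

    Path(path).write_text(json.dumps(obj, indent=1, default=_default, sort_keys=True))


def plot_mean_series(series, path) -> None:
    """Mean free/bound/internalized/total concentration vs time."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for col, style in (("C_F", "-"), ("C_B", "--"), ("C_I", ":"), ("C_T", "-.")):
        ax.plot(series["t"] / 60.0, series[col], style, label=col)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("mean concentration (mol/m$^3$)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_profiles(profiles, path, ylabel="value") -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, df in profiles.items():
        ax.plot(df["s"], df["value"], label=label)
    ax.set_xlabel("arc length along axis (mm)")
    ax.set_ylabel(ylabel)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_fk_series(t, fk, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(np.asarray(t) / 60.0, fk)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("fraction of killed cells")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
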