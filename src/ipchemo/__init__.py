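"""ipchemo: image-based modelling of intraperitoneal chemotherapy.

Steady intravascular + interstitial (Darcy/Starling) fluid flow in a 2D
tumor with an explicit heterogeneous vessel network, coupled to transient
convection-diffusion-reaction transport of free/bound/internalized
Doxorubicin, with treatment-efficacy metrics (AUC, half-width penetration
W_1/2, fraction of killed cells).
"""

from .errors import IPChemoError
from .units import mmhg_to_pa

__version__ = "0.1.0"


def __getattr__(name):
    # lazy imports keep `import ipchemo` light for CLI startup
    import importlib

    submodules = {
        "imaging", "geometry", "meshing", "fem", "flow", "transport",
        "metrics", "config", "pipeline", "io", "cli",
    }
    if name in submodules:
        return importlib.import_module(f".{name}", __name__)
    convenience = {
        "VesselNetwork": ("imaging", "VesselNetwork"),
        "generate_synthetic_network": ("imaging", "generate_synthetic_network"),
        "build_tumor_geometry": ("geometry", "build_tumor_geometry"),
        "generate_mesh": ("meshing", "generate_mesh"),
        "TissueParams": ("flow", "TissueParams"),
        "DrugParams": ("transport", "DrugParams"),
        "solve_interstitial": ("flow", "solve_interstitial"),
        "run_transport": ("transport", "run_transport"),
        "run_pipeline": ("pipeline", "run_pipeline"),
        "validate_config": ("config", "validate_config"),
    }
    if name in convenience:
        mod, attr = convenience[name]
        return getattr(importlib.import_module(f".{mod}", __name__), attr)
    raise AttributeError(f"module {__name__!r} has no attribute {name!r}")


__all__ = [
    "IPChemoError",
    "mmhg_to_pa",
    "__version__",
    "VesselNetwork",
    "generate_synthetic_network",
    "build_tumor_geometry",
    "generate_mesh",
    "TissueParams",
    "DrugParams",
    "solve_interstitial",
    "run_transport",
    "run_pipeline",
    "validate_config",
]
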