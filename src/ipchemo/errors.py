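"""Exception hierarchy for the simulation pipeline.

Each error carries a short machine-readable code (the ``code`` attribute)
so pipeline drivers can report which stage failed without parsing messages.
"""


class IPChemoError(Exception):
    """Base class for all package errors."""

    code = "error"

    def __init__(self, message: str = "", **context):
        self.context = context
        super().__init__(message or self.code)


class NoForegroundError(IPChemoError):
    """Binarization found no separable vessel foreground."""

    code = "no-foreground"


class NoVesselsError(IPChemoError):
    """Mask contains no connected component above the area floor."""

    code = "no-vessels"


class GeometryInfeasibleError(IPChemoError):
    """Requested synthetic network cannot fit the ellipse."""

    code = "geometry-infeasible"


class UnderResolvedError(IPChemoError):
    """Pixel size too coarse to resolve the channel width."""

    code = "under-resolved"


class GeometryClashError(IPChemoError):
    """Vessel lumen crosses the tumor surface."""

    code = "geometry-clash"


class MeshFailureError(IPChemoError):
    """Mesh generation produced an invalid triangulation."""

    code = "mesh-failure"


class IsolatedLumenError(IPChemoError):
    """A lumen component has no inlet/outlet terminal."""

    code = "isolated-lumen"


class SolverDivergedError(IPChemoError):
    """Linear/nonlinear solve failed to reach the residual tolerance."""

    code = "solver-diverged"


class NotSolvedError(IPChemoError):
    """Summary requested before the corresponding solve."""

    code = "not-solved"


class UnstableStepError(IPChemoError):
    """Time step violates the positivity/CFL guard."""

    code = "unstable-step"


class InvalidConcentrationError(IPChemoError):
    """Negative concentration passed to a pharmacodynamic formula."""

    code = "invalid-concentration"


class BadSeriesError(IPChemoError):
    """Time series not strictly increasing in t."""

    code = "bad-series"


class AxisOutsideError(IPChemoError):
    """Sampling axis does not intersect the domain."""

    code = "axis-outside"


class ConfigError(IPChemoError):
    """Configuration value failed validation."""

    code = "config-error"
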