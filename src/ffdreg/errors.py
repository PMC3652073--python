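"""Exception hierarchy shared across the package."""


class FFDRegError(Exception):
    """Base class for all package errors."""


class FormatError(FFDRegError):
    """Unreadable file, non-3D data, or invalid geometry metadata."""


class DegenerateInputError(FFDRegError):
    """Input carries no usable signal (e.g. constant volume for an edge map)."""


class SpecError(FFDRegError):
    """Invalid phantom or run specification."""


class FixtureError(FFDRegError):
    """Ground-truth deformation fixture could not be generated (e.g. grid fold)."""


class TopologyError(FFDRegError):
    """Mask or mesh violates the topology the pipeline requires."""


class EvolutionError(FFDRegError):
    """Active-surface evolution failed; carries the trace up to the failure."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


class OutOfSupportError(FFDRegError):
    """Point(s) outside the FFD grid support."""

    def __init__(self, message, offenders=None):
        super().__init__(message)
        self.offenders = offenders


class SolverError(FFDRegError):
    """Least-squares solve failed to converge; carries the iterate trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


class WarpError(FFDRegError):
    """Volume warping failed (empty ROI, folded deformation, ...)."""


class GeometryError(FFDRegError):
    """Volumes do not share a usable common world frame."""


class MetricError(FFDRegError):
    """Metric undefined for the given input (empty masks, zero dynamic range)."""
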