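"""Exception hierarchy for headfield.

All package errors derive from :class:`HeadfieldError` so callers can catch
broadly; most also derive from the matching builtin (ValueError/RuntimeError)
so generic handling keeps working.
"""


class HeadfieldError(Exception):
    """Base class for all headfield errors."""


class InvalidGeometryError(HeadfieldError, ValueError):
    """Phantom geometry parameters are inconsistent (e.g. non-decreasing radii)."""


class BoundsError(HeadfieldError, ValueError):
    """Requested geometry does not fit inside the voxel grid."""


class InvalidTransformError(HeadfieldError, ValueError):
    """Affine transform is singular, reflecting, or malformed."""


class PlacementError(HeadfieldError, RuntimeError):
    """Electrode placement could not produce disjoint scalp patches."""


class CapacityError(HeadfieldError, ValueError):
    """More samples requested than the phantom can provide."""


class TopologyError(HeadfieldError, ValueError):
    """Conducting region is not a single 6-connected component."""


class SolverError(HeadfieldError, RuntimeError):
    """Linear solve failed to converge; carries the final residual."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class EvaluationError(HeadfieldError, ValueError):
    """Field/potential evaluation requested outside the valid domain."""


class InvalidSubsetError(HeadfieldError, ValueError):
    """Electrode subset too small or referencing unknown electrodes."""


class UndefinedMetricError(HeadfieldError, ValueError):
    """Metric undefined for the given inputs (zero lead field, empty union...)."""


class DegenerateObjectiveError(HeadfieldError, ValueError):
    """Targeting objective is identically zero (no controllability at target)."""


class MontageCompatibilityError(HeadfieldError, ValueError):
    """Montage electrodes do not match the lead field's electrodes."""


class ScanError(HeadfieldError, RuntimeError):
    """Subspace scan failed (degenerate lead field at every location)."""


class FormatError(HeadfieldError, ValueError):
    """File does not conform to the documented on-disk format."""


class ConfigError(HeadfieldError, ValueError):
    """Run configuration outside documented parameter ranges."""


class TruncationWarning(UserWarning):
    """Analytic series did not pass its convergence ratio test."""
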