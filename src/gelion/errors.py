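"""Exception hierarchy for gelion.

Exit-code mapping used by the CLI:
  2 -> usage / configuration errors (click usage errors included)
  1 -> runtime errors (placement, instability, solver failures)
  3 -> analysis-quality failures (refused fits, unresolvable estimates)
"""


class GelionError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GelionError):
    """Invalid or inconsistent user-supplied configuration."""


class ConnectivityError(ConfigurationError):
    """Gel connectivity map incompatible with the requested architecture."""


class PlacementError(GelionError):
    """Random ion insertion failed (box too crowded)."""


class NeutralityError(GelionError):
    """System is not electroneutral where neutrality is required."""


class InstabilityError(GelionError):
    """Integration became unstable (NaN, overflow or displacement guard)."""

    def __init__(self, message, step=None, state=None):
        super().__init__(message)
        self.step = step
        self.state = state


class AnalysisError(GelionError):
    """Analysis could not produce a usable estimate."""


class FitRefusedError(AnalysisError):
    """Scaling fit refused (too few points, collinear or invalid data)."""
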