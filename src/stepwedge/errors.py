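"""Exception hierarchy for the step-wedge QA toolkit."""


class StepWedgeError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(StepWedgeError):
    """Invalid machine/phantom configuration."""


class AcquisitionFormatError(StepWedgeError):
    """Malformed acquisition file (bad header, row mismatch, negative signal)."""


class MonitorSignalError(StepWedgeError):
    """Monitor-chamber signal unusable (non-positive inside the beam-on segment)."""


class SegmentTooShortError(StepWedgeError):
    """A flat profile segment is too short to average transverse profiles from."""


class NoStepStructureError(StepWedgeError):
    """Time profile shows no detectable step-wedge structure."""


class FitQualityError(StepWedgeError):
    """A least-squares fit converged but failed its quality gate (R^2 <= 0.99).

    Carries the offending fit object (when one could be built) so it can be
    inspected.
    """

    def __init__(self, message, fit=None):
        super().__init__(message)
        self.fit = fit


class AbutmentError(StepWedgeError):
    """The completion/abutment analysis cannot be performed on these profiles."""


class SimulationError(StepWedgeError):
    """Inconsistent simulation scenario."""
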