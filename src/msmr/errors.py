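"""Exception hierarchy for the msmr package.

Each pipeline stage maps to a distinct exception class so the CLI can
return a distinct exit code per failure class.
"""


class MSMRError(Exception):
    """Base class for all msmr errors."""


class ConfigError(MSMRError):
    """Invalid configuration or invalid argument values."""


class SimulationError(MSMRError):
    """Simulator-stage failure (invalid simulation config)."""


class ProcessingError(MSMRError):
    """Trace-processing failure (malformed trace, rebin mismatch)."""


class UndefinedQError(ProcessingError):
    """Mandel Q is undefined because the mean count is zero."""


class InsufficientDataError(ProcessingError):
    """Too few valid sampling times to build or fit a curve."""


class CorrectionError(MSMRError):
    """Detector/background correction failure."""


class CorrectionInvalidError(CorrectionError):
    """Moment correction validity condition <k>*delta << 1 grossly violated."""


class CorrectionUndefinedError(CorrectionError):
    """Background correction undefined (background >= signal)."""


class FitError(MSMRError):
    """Fitting-stage failure (degenerate curve, no converged replicates)."""


class FormatError(MSMRError):
    """Malformed trace/curve/config file."""
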