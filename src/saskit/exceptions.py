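"""Exception hierarchy shared by all saskit modules."""


class SaskitError(Exception):
    """Base class for all saskit errors."""


class FormatError(SaskitError):
    """A file could not be parsed as the expected dialect."""


class GridError(SaskitError):
    """Frames of a series do not share a common momentum-transfer grid."""


class DataError(SaskitError):
    """Input data do not satisfy the preconditions of an analysis."""


class DetectionError(SaskitError):
    """Automatic region/peak detection found no admissible answer."""


class DecompositionError(SaskitError):
    """Matrix decomposition (EFA/rotation) failed or is ill-posed."""


class FitError(SaskitError):
    """Nonlinear least squares did not converge.

    The optimiser's last iterate is attached as ``last_iterate`` so a
    caller can inspect or restart from it.
    """

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate
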