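"""Exception types shared across the package."""


class ConnebmError(Exception):
    """Base class for all package errors."""


class InvalidConnectomeError(ConnebmError, ValueError):
    """Adjacency matrix violates the connectome contract (negativity, asymmetry, ...)."""


class InvalidTruthError(ConnebmError, ValueError):
    """A synthetic ground-truth object is internally inconsistent."""


class DegenerateDensityError(ConnebmError, ValueError):
    """A density fit was requested on data with no spread."""


class CovariateCollinearityError(ConnebmError, ValueError):
    """Covariate design matrix is rank deficient on the fitting set."""


class DegenerateBiomarkerError(ConnebmError, ValueError):
    """A biomarker has zero variance in the control group."""


class NumericalError(ConnebmError, ArithmeticError):
    """An iterative routine failed to converge or a likelihood underflowed to zero."""


class NoEventsError(ConnebmError, ValueError):
    """An EBM variant was requested with an empty event list."""
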