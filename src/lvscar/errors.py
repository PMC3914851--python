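"""Exception types shared across the package."""


class LVScarError(Exception):
    """Base class for all package errors."""


class InvalidKinematicsError(LVScarError):
    """A deformation quantity violates positivity or admissibility."""


class DegenerateGeometryError(LVScarError):
    """A geometric configuration has no physical interpretation."""


class SolverError(LVScarError):
    """Newton iteration failed to converge.

    Carries the last iterate and residual vector for diagnosis.
    """

    def __init__(self, message, state=None, residual=None, n_iter=None):
        super().__init__(message)
        self.state = state
        self.residual = residual
        self.n_iter = n_iter


class OutOfRangeError(LVScarError):
    """A query point lies outside the span of a computed curve."""


class InvalidParameterError(LVScarError):
    """A material or distribution parameter is outside its admissible range."""


class FitError(LVScarError):
    """Least-squares parameter estimation failed or is ill-posed."""
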