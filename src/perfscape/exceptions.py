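"""Exception types shared across the package."""


class PerfscapeError(Exception):
    """Base class for package-specific errors."""


class DegenerateScaleError(PerfscapeError, ValueError):
    """A standardization was requested on a vector with no usable scale
    (constant for min-max, zero mean for mean-standardization)."""


class SingularDesignError(PerfscapeError, ValueError):
    """The quadratic design matrix is rank deficient; carries the names of
    the collinear columns when they can be identified."""

    def __init__(self, message: str, collinear: tuple[str, ...] = ()):
        super().__init__(message)
        self.collinear = collinear


class SchemaError(PerfscapeError, ValueError):
    """An input table does not match the expected column schema."""

    def __init__(self, message: str, missing: tuple[str, ...] = ()):
        super().__init__(message)
        self.missing = missing


class GridMismatchError(PerfscapeError, ValueError):
    """Two landscape grids do not share the same (x, y) template and
    therefore cannot be compared; re-grid onto a common domain first."""


class QuadratureError(PerfscapeError, RuntimeError):
    """Adaptive quadrature failed to reach the requested tolerance; carries
    the best estimate and its error bound."""

    def __init__(self, message: str, estimate: float, error_bound: float):
        super().__init__(message)
        self.estimate = estimate
        self.error_bound = error_bound
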