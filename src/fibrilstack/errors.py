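"""Exception hierarchy shared by all analysis stages."""


class FibrilstackError(Exception):
    """Base class for all package errors."""


class FormatError(FibrilstackError, ValueError):
    """A file or record does not conform to the expected layout."""


class SizeError(FibrilstackError, ValueError):
    """An input has too few points for the requested operation."""


class DuplicateKeyError(FormatError):
    """A (residue number, atom) key occurs more than once in a shift table."""


class EmptyTableError(FormatError):
    """A shift table contains no usable entries."""


class DomainError(FibrilstackError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class GridError(FibrilstackError, ValueError):
    """Two sampled quantities live on incompatible wavelength/ppm grids."""


class FitFailureError(FibrilstackError, RuntimeError):
    """A nonlinear fit failed to converge or the data are degenerate.

    Carries ``best_residual`` when a partial solution was reached.
    """

    def __init__(self, message: str, best_residual: float | None = None):
        super().__init__(message)
        self.best_residual = best_residual
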