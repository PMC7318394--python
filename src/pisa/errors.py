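"""Exception hierarchy.

Everything raised deliberately by this package derives from :class:`PisaError`,
so callers (and the CLI) can distinguish input/validation problems from
computation problems.
"""


class PisaError(Exception):
    """Base class for all package errors."""


class ConfigError(PisaError):
    """Invalid run configuration (caught before any computation)."""


class FormatError(PisaError):
    """Input file does not have the expected columns/layout."""


class ParseError(PisaError):
    """A cell could not be converted to a number; message names the row."""


class EmptyInputError(PisaError):
    """A declared arm has no data rows."""


class DegenerateCurveError(PisaError):
    """Fewer than two usable points survive cleaning."""


class CoverageError(PisaError):
    """Raw curve ends before the requested study duration."""


class GridError(PisaError):
    """Time grid is non-uniform or two curves do not share a grid."""


class InsufficientDataError(PisaError):
    """Fit window contains too few points."""


class DegenerateFitError(PisaError):
    """Fit target is identically zero (nothing to fit)."""


class DomainError(PisaError):
    """Argument outside the mathematical domain of the operation."""


class MonotonicityError(PisaError):
    """Power fit is non-decreasing: no guaranteed threshold crossing."""
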