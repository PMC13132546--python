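"""Exception hierarchy shared across the package."""


class DepscreenError(Exception):
    """Base class for all package errors."""


class FormatError(DepscreenError):
    """A file could not be parsed (malformed header, bad token, wrong layout)."""


class ValidationError(DepscreenError):
    """Parsed content violates an invariant (duplicates, empty input, bad shape)."""


class GeneLookupError(DepscreenError, KeyError):
    """A requested gene symbol is absent from (or ambiguous in) a matrix."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return Exception.__str__(self)


class ParameterError(DepscreenError, ValueError):
    """An argument is outside its documented domain."""


class AlignmentError(DepscreenError):
    """Sensorgram time grids do not match; no silent interpolation is performed."""


class FitError(DepscreenError):
    """A model fit failed outright (non-convergence, inconsistent sign)."""


class DegenerateFitError(FitError):
    """The data carry no usable signal for the requested fit (flat trace, all-zero run)."""


class InsufficientDataError(FitError):
    """Too few points / concentrations / runs to attempt the fit."""
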