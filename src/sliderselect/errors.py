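"""Exception hierarchy.

Config-side problems (bad constraints, unknown facets, malformed panel
definitions) and data-side problems (bad files, mismatched feature
universes) are kept distinct so the CLI can map them to different exit
codes.
"""


class SliderSelectError(Exception):
    """Base class for all package errors."""


class ValidationError(SliderSelectError):
    """A container invariant is violated (negative value, duplicate id...)."""


class MappingError(SliderSelectError):
    """A facet map refers to a sample that the matrix does not contain."""


class ConfigurationError(SliderSelectError):
    """A constraint or panel definition is invalid or names an unknown facet."""


class DataError(SliderSelectError):
    """Inputs are individually valid but mutually inconsistent."""


class FormatError(SliderSelectError):
    """A file could not be parsed; carries a line number where known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class UnknownGeneError(SliderSelectError, LookupError):
    """Gene symbol absent from the annotation; carries close-match suggestions."""

    def __init__(self, symbol: str, suggestions: list[str]):
        self.symbol = symbol
        self.suggestions = suggestions
        hint = f"; did you mean: {', '.join(suggestions)}?" if suggestions else ""
        super().__init__(f"unknown gene symbol {symbol!r}{hint}")


class UnknownChromosomeError(SliderSelectError, LookupError):
    """Chromosome absent from the reference FASTA."""
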