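"""Exception hierarchy and warning categories."""


class CountemError(Exception):
    """Base class for all package-specific errors."""


class ParseError(CountemError):
    """A line of a count table could not be parsed."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class ValidationError(CountemError):
    """A parsed value violates a model invariant."""


class NoDataError(CountemError):
    """Estimation was requested on a table with no informative counts."""


class DegenerateDataError(CountemError):
    """A sample has zero posterior mass under every genotype."""


class UndefinedStatisticError(CountemError):
    """A derived statistic is undefined for the given estimates."""


class InfiniteBiasError(CountemError):
    """Pooled heterozygote counts imply an infinite sampling bias.

    Substitute a large finite value (e.g. 1e6); extreme bias values are
    effectively interchangeable at low coverage.
    """


class LowInformationWarning(UserWarning):
    """Error-rate co-estimation requested on data unlikely to support it."""


class ApproximateBiasWarning(UserWarning):
    """A size-regression bias estimate is only a rough first approximation."""
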