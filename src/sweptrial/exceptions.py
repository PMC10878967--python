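"""Exception hierarchy for sweptrial."""


class SweptrialError(Exception):
    """Base class for all package-specific errors."""


class DesignInfeasibleError(SweptrialError):
    """The stepped-wedge geometry cannot support the requested computation."""


class ValidationError(SweptrialError, ValueError):
    """An input record or parameter violates a documented invariant."""


class AliasingError(SweptrialError):
    """The design matrix is rank deficient; carries the aliased columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; aliased columns: "
            + ", ".join(map(str, self.columns))
        )


class NumericalSingularityError(SweptrialError):
    """A matrix required by the variance computation is numerically singular."""


class InfeasibleCorrelationError(SweptrialError):
    """The requested ICC/CAC targets cannot be induced at the given baseline."""


class SchemaError(SweptrialError):
    """A dataset does not conform to the package data dictionary."""


class InferenceInfeasibleError(SweptrialError):
    """Too few clusters for the requested inference (bootstrap or t reference)."""
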