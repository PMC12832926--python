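"""Exception hierarchy shared across the package."""


class CardioPSOError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(CardioPSOError, ValueError):
    """A table or CSV file violates the cohort schema."""


class DomainError(CardioPSOError, ValueError):
    """An operation was called on input outside its mathematical domain
    (empty column, constant vector for a correlation, absent class, ...)."""


class DegenerateVarianceError(DomainError):
    """A statistical test received differences with zero variance."""


class FitnessEvaluationError(CardioPSOError, RuntimeError):
    """The fitness callable raised during swarm optimization.

    Carries the offending normalized position so failed evaluations can be
    reproduced outside the optimizer loop.
    """

    def __init__(self, position, original: BaseException):
        self.position = position
        super().__init__(
            f"fitness evaluation failed at position {list(position)!r}: {original!r}"
        )
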