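"""Exception hierarchy shared across the package."""


class GranopartError(Exception):
    """Base class for all package errors."""


class ReferenceError_(GranopartError):
    """An identifier refers to a type or instance that does not exist."""


class OrderError(GranopartError):
    """A graph operation received input violating its order precondition
    (e.g. a cyclic edge set passed to transitive reduction)."""


class PreconditionError(GranopartError):
    """An operation precondition was violated by the caller."""


class PartitionError(GranopartError):
    """Successive partitions partially overlap or do not refine each other."""


class PerspectiveError(GranopartError):
    """A granularity perspective cannot be built (e.g. fewer than two levels)."""


class ClassificationError(GranopartError):
    """A parthood edge does not match any granulation criterion."""


class AnnotationError(GranopartError):
    """Required kind metadata (e.g. a name-giving object type) is missing."""


class ConsistencyError(GranopartError):
    """Value propagation derived two conflicting values for one level."""


class ParameterError(GranopartError):
    """Generator parameters are jointly unsatisfiable."""


class FixtureLookupError(GranopartError):
    """Unknown bundled fixture name."""


class SchemeLookupError(GranopartError):
    """A type id is unknown to an external scheme."""


class SchemeError(GranopartError):
    """An external scheme violates its own structural contract
    (e.g. one type listed in two levels)."""


class ParseError(GranopartError):
    """A document or flat file could not be parsed; carries a location."""

    def __init__(self, message: str, location: str | None = None):
        self.location = location
        super().__init__(message if location is None else f"{location}: {message}")


class OrderViolationError(GranopartError):
    """Raised by strict parsing when a document fails strict-partial-order
    validation; the offending :class:`~granopart.core_model.OrderReport`
    is attached as ``report``."""

    def __init__(self, report):
        self.report = report
        super().__init__(f"partonomy is not a valid strict partial order: {report}")
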