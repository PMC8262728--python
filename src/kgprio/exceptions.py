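"""Exception hierarchy.

Every error raised by this package derives from :class:`KgprioError` so
callers (and the CLI) can catch package failures in one place while still
distinguishing the stage that failed.
"""


class KgprioError(Exception):
    """Base class for all package errors."""


class FormatError(KgprioError):
    """An input file does not follow the expected layout."""


class EmptyInputError(KgprioError):
    """An input was empty after filtering."""


class ConsistencyError(KgprioError):
    """Graphs to be merged disagree on node identity or kind."""


class UnknownPhenotypeError(KgprioError):
    """A requested phenotype is absent from the disease-gene graph."""

    def __init__(self, phenotype: str, near_matches: list[str]):
        self.phenotype = phenotype
        self.near_matches = list(near_matches)
        hint = f" (similar: {', '.join(near_matches)})" if near_matches else ""
        super().__init__(f"phenotype {phenotype!r} not found in the graph{hint}")


class EmptySeedError(KgprioError):
    """Seed resolution produced no usable seed genes."""


class NodeNotFoundError(KgprioError):
    """A node id was looked up that is not in the graph."""


class DomainError(KgprioError):
    """Arguments violate the mathematical domain of an operation."""


class TrainingError(KgprioError):
    """Model training cannot proceed (no predictors, no seeds in matrix, ...)."""


class MetricUndefinedError(KgprioError):
    """A metric is undefined for the given labels (no positives or no negatives)."""


class ConfigurationError(KgprioError):
    """A job or generator configuration violates its contract."""
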