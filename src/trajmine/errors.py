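"""Exception hierarchy for trajectory mining.

Every stage raises a subclass of :class:`TrajmineError` so callers can
distinguish data problems from programming errors.
"""


class TrajmineError(Exception):
    """Base class for all package errors."""


class FormatError(TrajmineError):
    """Interchange file violates the expected layout (e.g. missing column)."""


class RowError(TrajmineError):
    """A single row of an interchange file could not be parsed."""

    def __init__(self, row_index: int, message: str):
        self.row_index = row_index
        super().__init__(f"row {row_index}: {message}")


class CodingError(TrajmineError):
    """A diagnosis code does not match the ICD-9-CM lexical shape."""


class RecordError(TrajmineError):
    """An admission record violates its invariants."""


class ConfigurationError(TrajmineError):
    """A policy or pipeline configuration is inconsistent with the data."""


class UndefinedStatisticError(TrajmineError):
    """A statistic is undefined for the given counts (e.g. zero incidence)."""


class AcyclicityError(TrajmineError):
    """Directed-pair input would induce a cycle in a trajectory graph."""
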