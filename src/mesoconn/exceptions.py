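"""Exception hierarchy for mesoconn.

All package errors derive from :class:`MesoconnError` so callers can catch
everything from one base, while the subclasses distinguish the broad failure
modes (bad file, bad value, bad configuration, degenerate statistics).
"""


class MesoconnError(Exception):
    """Base class for all mesoconn errors."""


class FormatError(MesoconnError):
    """A file could not be parsed (ragged rows, duplicate ids, bad tokens)."""


class ValidationError(MesoconnError):
    """An in-memory object violates an invariant (e.g. negative raw values)."""


class AssemblyError(MesoconnError):
    """Matrices/metadata could not be reconciled into a Dataset."""


class ConfigError(MesoconnError):
    """An operation was configured with impossible parameters."""


class EmptyDatasetError(MesoconnError):
    """Filtering removed every brain area."""


class ImputationError(MesoconnError):
    """A column had no observed values to impute from."""


class UndefinedStatisticError(MesoconnError):
    """A statistic is undefined for the given input (e.g. constant vector)."""
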