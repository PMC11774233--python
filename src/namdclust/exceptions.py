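"""Exception hierarchy shared across the package.

Grouped so the command-line layer can map failures onto exit codes:
configuration problems, data/schema problems, and numerical failures.
"""


class NamdclustError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(NamdclustError):
    """Invalid configuration or parameter combination."""


class DataError(NamdclustError):
    """Problems with input data (files, schemas, lookups)."""


class ParseError(DataError):
    """A trajectory or property file could not be parsed."""


class SchemaError(DataError):
    """A table is missing mandatory columns."""


class EmptyEnsembleError(DataError):
    """No frames survived ingestion/merging."""


class FrameLookupError(DataError):
    """A requested (trajectory, time) key does not exist."""


class ConnectivityError(NamdclustError):
    """The neighborhood graph of an embedding is disconnected."""


class NumericalError(NamdclustError):
    """A numerical procedure failed (singular covariance, degenerate affinity...)."""
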