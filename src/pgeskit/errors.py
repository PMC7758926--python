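"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit codes (argument -> 2, schema -> 3,
I/O/format -> 4), so keep the split between argument-, schema- and
I/O-shaped failures intact when raising.
"""


class PgesError(Exception):
    """Base class for all package-specific errors."""


class ArgumentError(PgesError, ValueError):
    """A caller-supplied parameter is invalid (bad band edges, bad split...)."""


class SchemaError(PgesError):
    """Structured input does not match the expected schema (channel labels,
    feature-name mismatch between a model and a feature table, ...)."""


class FormatError(PgesError):
    """A file exists but cannot be parsed in the declared format."""


class MontageError(PgesError):
    """A bipolar derivation references an electrode absent from the recording."""


class MetricError(PgesError):
    """An evaluation metric is undefined for the given inputs (single class)."""


class TrainingError(PgesError):
    """Model fitting cannot proceed (single-class labels, non-finite features)."""


class PersistenceError(PgesError):
    """A persisted model file is corrupt, truncated, or of unknown version."""
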