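"""Exception hierarchy shared across the pipeline stages."""


class SubwaveError(Exception):
    """Base class for all errors raised by subwave."""


class ConfigurationError(SubwaveError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class SchemaError(SubwaveError, ValueError):
    """A file does not match the expected CSV/JSON schema."""


class MembershipError(SubwaveError, ValueError):
    """A patient cannot be assigned to any subgroup (all baselines missing)."""


class TrainingError(SubwaveError, RuntimeError):
    """A model cannot be trained; the message names the subgroup."""


class MetricUndefinedError(SubwaveError, ValueError):
    """A performance metric is undefined for the given labels (single class)."""


class GridCellError(SubwaveError, RuntimeError):
    """A stage failed inside the evaluation grid; names the (level, gap) cell."""
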