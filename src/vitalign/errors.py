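"""Exception types shared across the package."""


class VitAlignError(Exception):
    """Base class for package errors."""


class DimensionError(VitAlignError):
    """Shape mismatch between an input and what the configuration expects."""


class ConfigurationError(VitAlignError):
    """Invalid configuration value."""


class InvalidLabelError(VitAlignError):
    """A label lies outside the space the model or metric can represent."""


class TrainingDivergenceError(VitAlignError):
    """Loss became non-finite during optimization."""


class DatasetError(VitAlignError):
    """A dataset directory or split is malformed."""


class EmptyInputError(VitAlignError):
    """An operation received no data."""


class InvalidSequenceError(VitAlignError):
    """A task sequence is malformed (e.g. an empty stage)."""
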