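"""Exception and warning types used across the package."""


class RescoreError(Exception):
    """Base class for all package-specific errors."""


class PinFormatError(RescoreError):
    """A PIN file violates the tab-delimited PSM table format."""


class SchemaError(RescoreError):
    """A feature schema is invalid or incompatible with a table/model."""


class ModelFileError(RescoreError):
    """A serialized model file is corrupt or cannot be parsed."""


class ModelVersionError(ModelFileError):
    """A serialized model declares an unsupported schema version."""


class SmallExperimentWarning(UserWarning):
    """Emitted when a dataset is below the recommended minimum size.

    Semi-supervised rescoring needs enough confident target PSMs to learn
    from; below roughly 5,000 total PSMs (assuming about one third can be
    assigned confidently) the learned model becomes unstable and a
    pretrained static model should be considered instead.
    """
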