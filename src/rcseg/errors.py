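"""Exception hierarchy for the RCS pipeline."""


class RCSError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(RCSError):
    """An argument or data structure violates a documented invariant."""


class InputError(RCSError):
    """A required input file is missing or cannot be decoded."""


class RegistrationError(RCSError):
    """Co-registration cannot proceed, e.g. an empty pre-segmentation."""


class TrainingError(RCSError):
    """A classifier ensemble cannot be trained on the given table."""


class ModelError(RCSError):
    """A persisted model bundle is missing, corrupt or incomplete."""


class ConfigurationError(RCSError):
    """An evaluation grid or run configuration is inconsistent."""
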