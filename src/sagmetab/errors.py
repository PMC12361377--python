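"""Exception hierarchy for sagmetab."""


class SagmetabError(Exception):
    """Base class for all package errors."""


class CatalogError(SagmetabError):
    """Invalid or inconsistent pathway catalog."""


class ConfigError(SagmetabError):
    """Invalid synthetic-community configuration."""


class IngestError(SagmetabError):
    """Malformed or incomplete input tables."""


class EstimationError(SagmetabError):
    """An estimator was asked for a quantity it cannot produce."""
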