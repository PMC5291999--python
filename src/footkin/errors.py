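"""Exception hierarchy.

Every error raised by footkin derives from :class:`FootkinError`, so callers
can catch the whole family with one clause.  Subclasses partition failures by
contract: bad configuration, degenerate geometry, malformed files, model
requirements not met, signal-processing preconditions, and internal contract
violations between pipeline stages.
"""


class FootkinError(Exception):
    """Base class for all footkin errors."""


class ConfigurationError(FootkinError):
    """Invalid configuration value (stance fraction, correlation, prevalence...)."""


class GeometryError(FootkinError):
    """Degenerate marker geometry: collinear or coincident points."""


class SchemaError(FootkinError):
    """File or label-registry schema violation (unknown labels, bad columns)."""


class ModelError(FootkinError):
    """Segment model requirement unmet (missing markers for a segment)."""


class SignalError(FootkinError):
    """Signal-processing precondition unmet (curve too short to filter...)."""


class ValidationError(FootkinError):
    """Invalid field value in a record (out-of-vocabulary category, duplicate id)."""


class NoStanceError(FootkinError):
    """No qualifying foot-contact interval in a force trace."""


class ContractError(FootkinError):
    """Inconsistent inputs passed between pipeline stages."""


class UndefinedCorrelationError(FootkinError):
    """Correlation requested on a zero-variance variable."""
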