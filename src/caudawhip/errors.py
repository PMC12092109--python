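"""Exception hierarchy for the caudawhip pipeline.

Every stage raises a subclass of :class:`CaudawhipError`, so callers
(including the CLI) can distinguish user-input problems from bugs.
"""


class CaudawhipError(Exception):
    """Base class for all caudawhip errors."""


class SchemaError(CaudawhipError):
    """A required column or config key is missing or unresolvable."""


class ValidationError(CaudawhipError):
    """A value violates a domain invariant (non-positive length, duplicate position, ...)."""


class ImputationError(CaudawhipError):
    """A missing vertebra cannot be imputed (no preserved neighbour on one side)."""


class SegmentationError(CaudawhipError):
    """No whip segment can be detected, or measurements near the crossing are absent."""


class ConfigError(CaudawhipError):
    """A run configuration is structurally invalid."""
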