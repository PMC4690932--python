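"""Typed exceptions and warnings shared across the toolkit.

All toolkit errors derive from :class:`SludgeKitError` so callers (and the
CLI) can distinguish data/validation failures (exit code 1) from usage
errors (exit code 2).
"""


class SludgeKitError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(SludgeKitError, ValueError):
    """Input data violates a documented invariant (bad value, bad shape)."""


class DomainError(SludgeKitError, ValueError):
    """Evaluation requested outside a model's validity domain."""


class InsufficientDataError(ValidationError):
    """Too few usable points/records for the requested fit."""


class InsufficientSpreadError(ValidationError):
    """Predictor values are degenerate (no spread to regress on)."""


class NoLinearZoneError(SludgeKitError):
    """No early window of a settling curve passes the linearity threshold."""


class NoOnsetError(SludgeKitError):
    """Curve lacks distinct hindered and compression zones."""


class NoIntersectionError(SludgeKitError):
    """Tangent-angle bisector does not meet the curve inside the record."""


class PlacementError(SludgeKitError):
    """Synthetic blob placement failed after bounded retries."""


class FormatError(SludgeKitError):
    """File does not match the documented CSV/JSON dialect."""


class SchemaError(SludgeKitError):
    """Serialized model document is missing or corrupting required fields."""


class ValidityWarning(UserWarning):
    """Evaluation outside a model's calibrated validity range."""


class FitWarning(UserWarning):
    """Fit succeeded but produced physically questionable parameters."""


class BoundaryMinimumWarning(UserWarning):
    """Flux minimum found at the edge of the searched concentration range."""
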