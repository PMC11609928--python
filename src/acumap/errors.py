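"""Exception hierarchy shared across the package."""


class AcumapError(Exception):
    """Base class for all package errors."""


class InvalidInputError(AcumapError):
    """Raised when inputs violate a documented precondition (non-finite
    coordinates, negative lengths, missing required fields, ...)."""


class DegenerateGeometryError(AcumapError):
    """Raised when a geometric construction is undefined (zero vector,
    coincident points, collinear plane frame)."""


class RegistryError(AcumapError):
    """Raised on rule-table parse/validation failures."""


class LookupError_(AcumapError):
    """Raised when an acupoint code is not present in a registry."""


class RuleEvaluationError(AcumapError):
    """Raised when a mapping rule cannot be evaluated against a landmark set."""


class PairingError(AcumapError):
    """Raised when a prediction and a ground-truth annotation cannot be paired."""


class SchemaError(AcumapError):
    """Raised when a file does not match its documented schema.

    ``path`` holds a JSON-path-like locator of the offending field.
    """

    def __init__(self, message: str, path: str = "$"):
        super().__init__(f"{path}: {message}")
        self.path = path
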