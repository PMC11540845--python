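"""Exception hierarchy shared across the package."""


class PgspartError(Exception):
    """Base class for package errors."""


class ConfigError(PgspartError):
    """Invalid configuration: missing columns, bad thresholds, bad specs."""


class InputDataError(PgspartError):
    """Input data unusable: zero valid rows, negative scale values, etc."""


class StructureError(PgspartError):
    """Structurally incompatible objects (mismatched frames, dimensions)."""


class DegenerateDataError(PgspartError):
    """Degenerate data: zero variance, empty partition, constant scores."""


class ConvergenceError(PgspartError):
    """Model fitting failed to converge (or showed quasi-separation)."""
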