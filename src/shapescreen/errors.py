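"""Exception types shared across the package."""


class ShapeScreenError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ShapeScreenError, ValueError):
    """A simulation or run configuration is internally inconsistent."""


class DegenerateDistributionError(ShapeScreenError, ValueError):
    """A per-well sample is constant (zero variance) and cannot be
    normalized; such wells are flagged and excluded from scoring."""


class FormatError(ShapeScreenError, ValueError):
    """An on-disk table violates the screen schema (missing wells,
    duplicate rows, non-numeric feature cells, ...)."""
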