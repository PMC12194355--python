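"""Exception hierarchy shared across the package."""


class ScintiDenoiseError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ScintiDenoiseError, ValueError):
    """Invalid configuration value or inconsistent hyperparameters."""


class DomainError(ScintiDenoiseError, ValueError):
    """Argument outside its mathematical domain (e.g. dose fraction > 1)."""


class ShapeError(ScintiDenoiseError, ValueError):
    """Array dimensions violate an operation's shape contract."""


class FormatError(ScintiDenoiseError, ValueError):
    """Unsupported on-disk image format or bit depth."""


class PairingError(ScintiDenoiseError, ValueError):
    """Low/full dose images cannot be paired (missing file, size mismatch)."""
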