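"""Exception types used across the package."""


class PricaError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(PricaError):
    """Invalid backbone / library / simulation configuration."""


class InputError(PricaError):
    """Missing or malformed input data (files, tables, structures)."""
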