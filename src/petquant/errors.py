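"""Exception hierarchy shared across the package."""


class PetquantError(Exception):
    """Base class for all petquant errors."""


class ValidationError(PetquantError, ValueError):
    """Input data violates a stated precondition or invariant."""


class FormatError(PetquantError, ValueError):
    """A file or sidecar is internally inconsistent (e.g. frame-count mismatch)."""


class ConfigError(PetquantError, ValueError):
    """Pipeline configuration is missing keys or names an unsupported variant."""


class FitError(PetquantError, RuntimeError):
    """A model fit failed to converge; the message carries the last iterate."""
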