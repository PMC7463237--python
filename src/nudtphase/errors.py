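"""Exception hierarchy shared across the pipeline stages."""


class NudtphaseError(Exception):
    """Base class for all package-specific errors."""


class HgvsParseError(NudtphaseError):
    """A cDNA HGVS string could not be parsed; the message names the offending token."""


class ReferenceValidationError(NudtphaseError):
    """The reference sequence does not carry the expected base at a panel site."""


class ConfigError(NudtphaseError):
    """Invalid simulation or pipeline configuration."""


class ValidationError(NudtphaseError):
    """Invalid input to an operation (length mismatches, empty groups, ...)."""


class LowDepthError(NudtphaseError):
    """No informative fragments: a diplotype call cannot be made."""


class AmbiguousCallError(NudtphaseError):
    """Fragment patterns do not support a confident one- or two-haplotype call."""
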