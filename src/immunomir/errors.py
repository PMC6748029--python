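"""Exception types shared across the pipeline."""


class ImmunomirError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ImmunomirError, ValueError):
    """A simulation or run configuration violates its invariants."""


class ParseError(ImmunomirError, ValueError):
    """An on-disk table is malformed; message names file and problem."""


class DegenerateReferenceError(ImmunomirError, ValueError):
    """Control reference statistics are unusable (sd == 0 or too few controls)."""


class UnclassifiableError(ImmunomirError, ValueError):
    """A subject has no valid ratio under any usable culture condition."""


class MissingPhaseError(ImmunomirError, ValueError):
    """An OCR trace lacks one of the protocol phases entirely."""
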