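"""Exception hierarchy shared across the package."""


class ImmunodynError(Exception):
    """Base class for all package errors."""


class FormatError(ImmunodynError):
    """A table or config file does not conform to the expected layout."""


class ValidationError(ImmunodynError):
    """Input values violate a precondition (negative counts, bad ranges...)."""


class EmptySampleError(ImmunodynError):
    """A repertoire sample has no productive templates; statistics refuse it."""


class ConflictError(ImmunodynError):
    """Two inputs claim the same identity (e.g. duplicate patient/visit)."""


class SimSpecError(ImmunodynError):
    """A simulation specification is internally inconsistent."""
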