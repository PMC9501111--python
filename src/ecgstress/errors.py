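"""Exception hierarchy shared across the package."""


class EcgStressError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(EcgStressError, ValueError):
    """A numeric parameter is outside its admissible range."""


class MorphologyError(EcgStressError, ValueError):
    """A beat-template morphology violates its geometric invariants."""


class FormatError(EcgStressError, ValueError):
    """An input file violates the expected on-disk format."""


class DataError(EcgStressError, ValueError):
    """Input data are too short, degenerate, or otherwise unusable."""
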