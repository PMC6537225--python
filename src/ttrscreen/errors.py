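"""Exception hierarchy for ttrscreen."""


class TTRScreenError(Exception):
    """Base class for all package-specific errors."""


class MutationParseError(TTRScreenError, ValueError):
    """A mutation string does not match the substitution grammar."""


class ReferenceMismatchError(TTRScreenError, ValueError):
    """The wild-type residue of a mutation disagrees with the reference sequence."""


class CatalogError(TTRScreenError, ValueError):
    """A variant catalogue could not be built or loaded."""


class ConfigError(TTRScreenError, ValueError):
    """Invalid configuration value or file."""


class SpectrumFormatError(TTRScreenError, ValueError):
    """A spectrum file could not be parsed."""


class InputDomainError(TTRScreenError, ValueError):
    """An input spectrum does not cover the required mass window."""


class CalibrationError(TTRScreenError, RuntimeError):
    """Too few calibrant peaks matched, or the fit is implausible."""


class DataIntegrityError(TTRScreenError, RuntimeError):
    """A bundled data fixture failed its checksum."""
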