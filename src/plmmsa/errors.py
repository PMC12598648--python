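"""Exception hierarchy for the plmmsa package."""


class PlmMsaError(Exception):
    """Base class for all plmmsa errors."""


class InvalidInputError(PlmMsaError, ValueError):
    """An argument violates a documented precondition."""


class InvalidAlphabetError(InvalidInputError):
    """A sequence contains characters outside the accepted amino-acid alphabet."""


class UndefinedSimilarityError(InvalidInputError):
    """Cosine similarity requested for a zero vector."""


class ConfigurationError(PlmMsaError):
    """Pipeline configuration is inconsistent or incomplete."""


class ParseError(PlmMsaError, ValueError):
    """A file could not be parsed; the message names the offending record."""
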