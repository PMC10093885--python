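"""Exception hierarchy shared across the package."""


class MednovaError(Exception):
    """Base class for all package-specific errors."""


class ParseError(MednovaError):
    """A food table file could not be parsed (names the offending record)."""


class ValidationError(MednovaError):
    """A food record violates the data-model invariants."""


class ConfigurationError(MednovaError):
    """A lexicon, score-table or pyramid-mapping config is invalid."""


class NotApplicable(MednovaError):
    """A statistical comparison cannot be run (group size < 2)."""
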