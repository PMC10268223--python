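"""Exception hierarchy."""


class IcukitError(Exception):
    """Base class for all package errors."""


class ConfigError(IcukitError):
    """Invalid source configuration (schema violation, duplicate names, ...)."""


class SchemaError(IcukitError):
    """Data files do not match the declared table schemas."""


class DictionaryError(IcukitError):
    """Invalid concept-dictionary document."""


class DependencyError(DictionaryError):
    """Cycle or unresolvable reference among recursive concepts."""


class ConceptLookupError(IcukitError, KeyError):
    """Requested concept not found in the dictionary."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message
        return Exception.__str__(self)


class AvailabilityError(IcukitError):
    """Concept has no extraction items declared for the requested source."""


class ExtractionError(IcukitError):
    """An item references a table or column absent from the source."""
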