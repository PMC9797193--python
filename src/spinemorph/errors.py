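"""Exception hierarchy shared across the package."""


class SpinemorphError(Exception):
    """Base class for all package errors."""


class InvalidInputError(SpinemorphError, ValueError):
    """An argument violates a documented precondition (bad geometry, bad config)."""


class DataIntegrityError(SpinemorphError, ValueError):
    """Tabular records are mutually inconsistent (orphan spines, broken groups)."""


class SchemaError(SpinemorphError, ValueError):
    """A required column is missing or cannot be mapped when reading tables."""


class InsufficientDataError(SpinemorphError, ValueError):
    """Too few observations for the requested statistical report."""
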