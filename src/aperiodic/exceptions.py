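"""Exception hierarchy.

``ConfigurationError`` covers invalid settings (indivisible trial counts,
nonsensical windows); ``InputError`` covers bad data handed to an operation;
``FitError`` covers degenerate fitting situations; ``DataError`` covers
inconsistent tables (duplicate cells, missing columns).
"""


class AperiodicError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AperiodicError):
    """Settings violate a structural requirement."""


class InputError(AperiodicError):
    """Data handed to an operation is invalid."""


class FitError(AperiodicError):
    """A model fit cannot be carried out."""


class DataError(AperiodicError):
    """A table is structurally inconsistent."""
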