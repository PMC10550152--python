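"""Exception hierarchy.

All errors raised by the library derive from :class:`MeadowTradeError` so the
CLI and pipeline can convert any stage failure into a labelled non-zero exit.
"""


class MeadowTradeError(Exception):
    """Base class for all meadowtrade errors."""


class ConfigurationError(MeadowTradeError):
    """Inconsistent or invalid configuration (design/effects mismatch, bad weights...)."""


class DomainError(MeadowTradeError):
    """An indicator or statistic is mathematically undefined for the given input."""


class SchemaError(MeadowTradeError):
    """An input table does not match its documented CSV schema."""
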