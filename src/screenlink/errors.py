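"""Exception hierarchy.

``DataError`` marks problems with user-supplied inputs (malformed tables,
unknown identifiers, insufficient overlap); the CLI maps it to exit status 1.
``CapabilityError`` marks a requested feature the installed backends cannot
provide; it is never silently downgraded to a fallback.
"""


class ScreenlinkError(Exception):
    """Base class for all package errors."""


class DataError(ScreenlinkError):
    """Invalid or insufficient input data."""


class CapabilityError(ScreenlinkError):
    """Requested operation unavailable with the installed backends."""
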