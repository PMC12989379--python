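"""Exception hierarchy. Every stage raises a subclass of OmicnetError."""


class OmicnetError(Exception):
    """Base class for all package errors."""


class ConfigError(OmicnetError):
    """Invalid configuration; the message names the offending field."""


class FormatError(OmicnetError):
    """Malformed input file (duplicate ids, bad values, short lines)."""


class AlignmentError(OmicnetError):
    """Sample sets cannot be aligned (empty intersection)."""


class ContrastError(OmicnetError):
    """A contrast group is empty or too small to test."""


class InsufficientDataError(OmicnetError):
    """Too few samples for the requested computation."""


class IntegrationError(OmicnetError):
    """Feature subset empty after filtering."""


class EnrichmentError(OmicnetError):
    """Query empty after restriction to the universe."""
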