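"""Exception hierarchy for diagsnp."""


class DiagsnpError(Exception):
    """Base class for all diagsnp errors."""


class ParseError(DiagsnpError):
    """A file could not be parsed; the message names the offending line."""


class BiallelicViolationError(DiagsnpError):
    """A marker carries more than two observed alleles; names the marker."""


class ConsistencyError(DiagsnpError):
    """Cross-table inconsistency (e.g. marker/fragment chromosome mismatch)."""


class ConfigurationError(DiagsnpError):
    """Invalid configuration (unknown taxon, empty reference group, bad fractions)."""
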