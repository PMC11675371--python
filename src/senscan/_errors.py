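"""Exception hierarchy shared across senscan modules."""


class SenscanError(Exception):
    """Base class for all senscan errors."""


class HgvsParseError(SenscanError, ValueError):
    """An HGVS protein notation could not be parsed.

    Carries the offending token so callers can report which part of the
    notation failed.
    """

    def __init__(self, notation: str, token: str, reason: str):
        self.notation = notation
        self.token = token
        self.reason = reason
        super().__init__(f"cannot parse {notation!r}: {reason} (offending token: {token!r})")


class RangeError(SenscanError, ValueError):
    """A residue or nucleotide coordinate is outside its valid range."""


class ConsequenceError(SenscanError, ValueError):
    """An operation received a variant of an inapplicable consequence class."""


class SchemaError(SenscanError, ValueError):
    """A tabular input file is missing required columns."""


class TranscriptValidationError(SenscanError, ValueError):
    """An exon/CDS model violates its structural invariants."""


class ConfigError(SenscanError, ValueError):
    """A configuration value is invalid (e.g. even smoothing window)."""


class SpecError(SenscanError, ValueError):
    """A synthetic-data specification is internally inconsistent."""
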