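"""Exception types shared across the pipeline."""


class AffinispaceError(Exception):
    """Base class for all package errors."""


class CorpusParseError(AffinispaceError):
    """A JSON-Lines record could not be parsed or validated.

    Carries the offending path and 1-based line number.
    """

    def __init__(self, path: str, line_no: int, reason: str):
        self.path = path
        self.line_no = line_no
        self.reason = reason
        super().__init__(f"{path}:{line_no}: {reason}")


class ReferentialIntegrityError(AffinispaceError):
    """A tweet references an author_id with no matching user record."""


class TagRejectedError(AffinispaceError):
    """A hashtag normalized to the empty string."""


class URLRejectedError(AffinispaceError):
    """A URL was rejected during domain extraction (unparseable or shortener)."""

    def __init__(self, url: str, reason: str):
        self.url = url
        self.reason = reason
        super().__init__(f"{url!r} rejected: {reason}")


class UndefinedMetricError(AffinispaceError):
    """A percentage or ratio has a zero denominator."""


class OutOfWindowError(AffinispaceError):
    """A tweet timestamp falls outside the requested analysis window."""


class InfeasibleTableError(AffinispaceError):
    """A deterministic table reconstruction has no valid tweet allocation."""


class ConfigError(AffinispaceError):
    """Pipeline configuration is missing keys or contains invalid values."""
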