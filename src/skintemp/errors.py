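"""Exception hierarchy."""


class SkinTempError(Exception):
    """Base class for all package errors."""


class ConfigError(SkinTempError, ValueError):
    """An invalid synthetic-cohort configuration field."""


class ParseError(SkinTempError, ValueError):
    """A malformed recording file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None else f"line {line}: {message}")


class AlignmentError(SkinTempError):
    """A subject's sensor time ranges cannot be brought onto a common grid."""


class MissingSiteError(SkinTempError, KeyError):
    """A required sensor site is absent from a recording."""

    def __init__(self, site, context: str = ""):
        self.site = site
        suffix = f" ({context})" if context else ""
        super().__init__(f"missing required site {getattr(site, 'value', site)}{suffix}")

    def __str__(self) -> str:
        return self.args[0]


class EmptyDesignError(SkinTempError):
    """No usable (group-complete) rows to build a design matrix from."""


class SingularDesignError(SkinTempError):
    """Design matrix is (numerically) rank deficient."""


class InsufficientSamplesError(SkinTempError, ValueError):
    """Too few samples for the requested statistic."""
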