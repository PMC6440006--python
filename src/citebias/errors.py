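"""Exception types shared across the package."""


class CitebiasError(Exception):
    """Base class for all package-specific errors."""


class CorpusSchemaError(CitebiasError):
    """A corpus file is structurally malformed (missing column, bad enum token)."""


class CorpusIntegrityError(CitebiasError):
    """Cross-record consistency is broken (dangling reference, duplicate id)."""


class CategorizationError(CitebiasError):
    """Tertile categorization is impossible (too few distinct values, tied cutoffs)."""


class ConfigError(CitebiasError):
    """An invalid run or generator configuration."""


class SeparationError(CitebiasError):
    """The likelihood is monotone in some coefficient (perfect prediction)."""


class NotEstimableError(CitebiasError):
    """A determinant cannot be estimated (empty category, no events)."""


class FitError(CitebiasError):
    """Model fitting failed for a reason other than separation."""
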