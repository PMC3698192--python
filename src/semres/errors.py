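"""Exception hierarchy for semres."""


class SemresError(Exception):
    """Base class for all semres errors."""


class RepositoryError(SemresError):
    """Structural problem in the concept repository (cycle, empty lex, bad probability)."""


class UnknownConceptError(SemresError, KeyError):
    """A concept id was looked up that the repository does not contain."""


class UndefinedScoreError(SemresError):
    """Every lexical variant of a concept has zero information, so sim is undefined."""


class ConfigurationError(SemresError):
    """Invalid configuration: facet map, pattern file, or ranking weights."""


class EstimationError(SemresError):
    """The topic model cannot be estimated (e.g. all resource vectors empty)."""


class RefinementError(SemresError):
    """Invalid vector refinement: unknown concepts or a replacement outside the taxonomy closure."""
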