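"""Exception hierarchy for the analysis pipeline.

Every stage raises a subclass of :class:`PromaError` so the CLI can attach a
stage name and exit with an actionable message.
"""


class PromaError(Exception):
    """Base class for all pipeline errors."""


class GPRFormatError(PromaError):
    """Malformed ATF/GPR text (preamble, header count, column row)."""


class GPRParseError(PromaError):
    """A data cell could not be parsed (e.g. non-numeric in a numeric column)."""


class IntegrityError(PromaError):
    """A within-file invariant is violated (e.g. duplicate spot coordinates)."""


class ConsistencyError(PromaError):
    """Files in one experiment disagree on columns or spot layout."""


class SelectionError(PromaError):
    """Foreground/background channels could not be chosen."""


class ContractError(PromaError):
    """An operation was called with inputs violating its stage/shape contract."""


class PanelError(PromaError):
    """Control-panel edit or lookup referenced an unknown protein."""


class DesignMatrixError(PromaError):
    """The control-model design matrix is rank deficient or degenerate."""


class MetadataError(PromaError):
    """Sample metadata could not be matched to the uploaded files."""


class DesignError(PromaError):
    """The sample/group design is too small or otherwise invalid."""


class AnalysisError(PromaError):
    """Differential analysis could not proceed (e.g. no usable proteins)."""


class ConfigError(PromaError):
    """Invalid synthetic-data or run configuration."""
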