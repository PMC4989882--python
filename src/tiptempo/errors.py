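"""Exception hierarchy for tiptempo.

All user-facing failures derive from :class:`TipTempoError` so that the CLI
can catch one type, print the message, and exit nonzero.
"""


class TipTempoError(Exception):
    """Base class for all tiptempo errors."""


class NewickParseError(TipTempoError):
    """Malformed newick input; message includes the character position."""


class DuplicateTipLabelError(TipTempoError):
    """Two or more tips share the same label."""


class NegativeBranchLengthError(TipTempoError):
    """A branch length is negative (and clamping was not requested)."""


class DateParseError(TipTempoError):
    """A date string could not be interpreted."""


class LabelExtractionError(TipTempoError):
    """One or more tip labels did not match the extraction rule.

    Carries ``labels``: the full list of offending labels.
    """

    def __init__(self, message: str, labels: list):
        super().__init__(message)
        self.labels = list(labels)


class DateConflictError(TipTempoError):
    """The same tip was assigned two different dates."""


class MissingDatesError(TipTempoError):
    """Tips present in the tree lack dates (or vice versa).

    Carries ``missing_in_dates`` and ``missing_in_tree``.
    """

    def __init__(self, message: str, missing_in_dates=(), missing_in_tree=()):
        super().__init__(message)
        self.missing_in_dates = sorted(missing_in_dates)
        self.missing_in_tree = sorted(missing_in_tree)


class IsochronousDataError(TipTempoError):
    """All sampling times identical: regression on time is undefined.

    The variance-of-root-to-tip-distances criterion (isochronous mode)
    is the appropriate analysis for such data.
    """


class DegenerateRegressionError(TipTempoError):
    """Too few points, or otherwise unfittable regression input."""
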