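"""Exception hierarchy for barcodegap.

All package-specific errors derive from :class:`BarcodeGapError` so callers
can catch one base class at pipeline boundaries.
"""


class BarcodeGapError(Exception):
    """Base class for all barcodegap errors."""


class FormatError(BarcodeGapError):
    """Input file is not in the expected format (e.g. not FASTA)."""


class LabelError(BarcodeGapError):
    """A taxonomic label could not be parsed from a sequence header."""


class AlignmentError(BarcodeGapError):
    """Sequences do not form a valid alignment (length mismatch etc.)."""


class DuplicateIdError(BarcodeGapError):
    """Two sequence records share the same identifier."""


class EmptyDatasetError(BarcodeGapError):
    """An operation produced or received a dataset with no records/columns."""


class MissingTaxonError(BarcodeGapError):
    """A genus or label cannot be resolved through the taxonomy map."""

    def __init__(self, offenders, level=None):
        self.offenders = sorted(set(offenders))
        self.level = level
        msg = "unresolvable taxa: " + ", ".join(self.offenders)
        if level:
            msg += f" (level={level})"
        super().__init__(msg)


class UndefinedDistanceError(BarcodeGapError):
    """A pairwise distance has zero comparable sites."""


class ImpreciseLabelError(BarcodeGapError):
    """An operation requiring species-level labels met an imprecise one."""


class EmptyBinError(BarcodeGapError):
    """Gap analysis requires both intraspecific and interspecific pairs."""


class TreeSizeError(BarcodeGapError):
    """Too few sequences for tree construction."""


class SimulationError(BarcodeGapError):
    """Invalid simulation specification or infeasible injection."""


class StageError(BarcodeGapError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage, cause):
        self.stage = stage
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
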