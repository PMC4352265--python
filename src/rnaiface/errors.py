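"""Exception hierarchy shared across the pipeline."""


class RnaIfaceError(Exception):
    """Base class for all package-specific errors."""


class ManifestError(RnaIfaceError):
    """A manifest entry is inconsistent with the structure file (e.g. missing chain)."""


class DatasetCriteriaError(RnaIfaceError):
    """A complex violates the dataset inclusion criteria (chain length minima)."""


class StructureError(RnaIfaceError):
    """A structure file cannot be parsed or written."""


class AlignmentError(RnaIfaceError):
    """Per-residue annotations do not align with the observed sequence."""


class SyntheticSpecError(RnaIfaceError):
    """A synthetic-complex specification is invalid or infeasible."""
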