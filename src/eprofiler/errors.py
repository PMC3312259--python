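"""Exception hierarchy for eprofiler."""


class EprofilerError(Exception):
    """Base class for all eprofiler errors."""


class FormatError(EprofilerError):
    """A file could not be parsed (PDB, stats TSV, profile text)."""


class EmptyStructureError(EprofilerError):
    """No canonical residues remained after filtering a coordinate file."""


class GeometryError(EprofilerError):
    """Degenerate geometry (e.g. collinear backbone atoms)."""


class TableLookupError(EprofilerError):
    """An amino acid is missing from a pseudoenergy table."""


class DegenerateDistributionError(EprofilerError):
    """An energy sample has zero variance; no quantile binning possible."""


class DegenerateNullError(EprofilerError):
    """Permutation null mean equals the optimal score; dScore undefined."""
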