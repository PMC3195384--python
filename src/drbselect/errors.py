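"""Exception hierarchy for drbselect."""


class DrbSelectError(Exception):
    """Base class for all drbselect errors."""


class FormatError(DrbSelectError):
    """Malformed or empty input file."""


class AlignmentError(DrbSelectError):
    """Sequences violate alignment invariants (unequal lengths, bad window)."""


class MaskError(DrbSelectError):
    """Invalid codon-partition mask (out-of-range or duplicate positions)."""


class PartitionApplicationError(DrbSelectError):
    """Partition does not match the alignment it is applied to."""


class UndefinedCodonError(DrbSelectError):
    """Codon is a stop codon or contains ambiguous/missing bases."""


class SaturationError(DrbSelectError):
    """Observed difference proportion outside the distance formula's domain."""


class NoDataError(DrbSelectError):
    """No usable sites or pairs remain after filtering."""


class DegenerateVarianceError(DrbSelectError):
    """Z-test requested with zero variance but unequal estimates."""


class MatrixError(DrbSelectError):
    """Distance matrix is not symmetric, finite and nonnegative."""
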