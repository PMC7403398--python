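"""Exception hierarchy shared across the package."""


class LethscanError(Exception):
    """Base class for all package errors."""


class FormatError(LethscanError):
    """Malformed input file (names the offending line where possible)."""


class TriallelicError(FormatError):
    """More than two distinct alleles observed at one variant."""


class MergeError(LethscanError):
    """Datasets cannot be merged (empty intersection, allele conflict)."""


class AlleleConflictError(MergeError):
    """Shared position with incompatible allele sets across datasets."""


class DegenerateVariantError(LethscanError):
    """Variant with no usable genotype calls."""


class UndefinedLDError(LethscanError):
    """LD undefined (monomorphic locus among double-nonmissing samples)."""


class InsufficientDataError(LethscanError):
    """Too few usable samples for a fit."""
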