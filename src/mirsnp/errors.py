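"""Exception hierarchy for mirsnp.

Every error raised on bad *data* (as opposed to programming mistakes)
derives from :class:`MirsnpError`, so callers can catch one type at the
CLI boundary and report the offending record.
"""


class MirsnpError(Exception):
    """Base class for all mirsnp data errors."""


class MalformedSequenceError(MirsnpError):
    """A nucleotide string contains a character outside {A,C,G,T,U,N}."""

    def __init__(self, seq: str, position: int):
        self.position = position
        super().__init__(
            f"invalid nucleotide {seq[position]!r} at position {position} "
            f"in sequence {seq!r}"
        )


class InvalidMiRNAError(MirsnpError):
    """A mature miRNA sequence is too short or otherwise unusable."""


class TooShortWindowError(MirsnpError):
    """An allele window is shorter than the minimum scannable length."""


class DuplicateIdentifierError(MirsnpError):
    """Two records share an identifier that must be unique."""


class InvalidThresholdError(MirsnpError):
    """A threshold parameter is outside its valid domain."""


class EmptyUniverseError(MirsnpError):
    """A contingency table or permutation universe would be empty."""


class EmptySampleError(MirsnpError):
    """A rank-based test received an empty sample."""


class InsufficientDataError(MirsnpError):
    """Too few paired observations to run an association test."""


class InconsistentInputError(MirsnpError):
    """Subset/superset or dimension relations between inputs are violated."""


class MissingMappingError(MirsnpError):
    """SNP identifiers lack a required SNP-to-gene mapping entry."""

    def __init__(self, snp_ids):
        self.snp_ids = sorted(snp_ids)
        shown = ", ".join(self.snp_ids[:10])
        more = "" if len(self.snp_ids) <= 10 else f" (+{len(self.snp_ids) - 10} more)"
        super().__init__(f"no gene mapping for SNPs: {shown}{more}")


class GeneratorExhaustedError(MirsnpError):
    """The synthetic-data generator failed to construct a record in its retry budget."""
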