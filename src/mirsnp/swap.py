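"""Allele-swapped window construction and regulation-change classification.

For a coding-region SNP the two alleles are each embedded at the centre of a
31-nt window (15 nt of flank on either side, taken on the mRNA sense
strand). Both windows are scanned for canonical seed-match sites; the SNP
*changes miRNA regulation* when the sets of binding miRNAs differ between
the two windows — i.e. at least one miRNA gains or loses a counted site
overlapping the variant base. Changes are counted at the miRNA level: a
variant that merely relocates a site of a miRNA that binds both alleles is
not a change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import pandas as pd

from .errors import DuplicateIdentifierError, TooShortWindowError
from .seeds import SeedCatalog, binding_mirnas, normalize_sequence

#: Flank length on each side of the variant base; 2*15 + 1 = 31-nt window.
FLANK_LENGTH = 15

#: Shortest window worth scanning (the longest site type is 8 nt).
MIN_WINDOW_LENGTH = 8

SnpClass = Literal["synonymous", "nonsynonymous"]
_ALLELES = frozenset("ACGT")


@dataclass(frozen=True)
class SnpRecord:
    """One biallelic coding-region SNP with its sense-strand flanks.

    Flanks are at most :data:`FLANK_LENGTH` nt each; shorter flanks are
    permitted (SNPs near transcript ends) and flagged by
    :meth:`has_full_flanks`. Alleles are single distinct ACGT bases on the
    mRNA sense strand.
    """

    snp_id: str
    left_flank: str
    right_flank: str
    allele_a: str
    allele_b: str
    snp_class: SnpClass = "synonymous"

    def __post_init__(self) -> None:
        object.__setattr__(self, "left_flank", normalize_sequence(self.left_flank))
        object.__setattr__(self, "right_flank", normalize_sequence(self.right_flank))
        for which in ("allele_a", "allele_b"):
            allele = getattr(self, which).upper()
            if allele not in _ALLELES:
                raise ValueError(f"{self.snp_id}: {which} {allele!r} not a single ACGT base")
            object.__setattr__(self, which, allele)
        if self.allele_a == self.allele_b:
            raise ValueError(f"{self.snp_id}: alleles must differ")
        for name, flank in (("left", self.left_flank), ("right", self.right_flank)):
            if len(flank) > FLANK_LENGTH:
                raise ValueError(
                    f"{self.snp_id}: {name} flank is {len(flank)} nt, max {FLANK_LENGTH}"
                )
        if self.snp_class not in ("synonymous", "nonsynonymous"):
            raise ValueError(f"{self.snp_id}: bad snp_class {self.snp_class!r}")

    def has_full_flanks(self) -> bool:
        return len(self.left_flank) == FLANK_LENGTH and len(self.right_flank) == FLANK_LENGTH

    @property
    def center_offset(self) -> int:
        """0-based offset of the variant base inside either allele window."""
        return len(self.left_flank)


@dataclass(frozen=True)
class RegulationChange:
    """Per-SNP verdict: which miRNAs bind one allele's window but not the other's.

    ``gained`` are miRNAs binding the b-allele window only, ``lost`` those
    binding the a-allele window only; ``changed`` iff either set is
    non-empty. With ref/alt inputs allele_a is conventionally the reference.
    """

    snp_id: str
    gained: frozenset[str]
    lost: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "gained", frozenset(self.gained))
        object.__setattr__(self, "lost", frozenset(self.lost))
        if self.gained & self.lost:
            raise ValueError(f"{self.snp_id}: gained and lost overlap")

    @property
    def changed(self) -> bool:
        return bool(self.gained or self.lost)


def build_allele_window(snp: SnpRecord, which_allele: Literal["a", "b"]) -> str:
    """Sense-strand window with the requested allele at the centre.

    With full flanks the window is 31 nt and the allele sits at offset 15.
    """
    if which_allele not in ("a", "b"):
        raise ValueError(f"which_allele must be 'a' or 'b', got {which_allele!r}")
    allele = snp.allele_a if which_allele == "a" else snp.allele_b
    window = snp.left_flank + allele + snp.right_flank
    if len(window) < MIN_WINDOW_LENGTH:
        raise TooShortWindowError(
            f"{snp.snp_id}: window is {len(window)} nt, need >= {MIN_WINDOW_LENGTH}"
        )
    return window


def classify_snp(snp: SnpRecord, catalog: SeedCatalog) -> RegulationChange:
    """Scan both allele windows and report gained/lost binding miRNAs."""
    bind_a = binding_mirnas(build_allele_window(snp, "a"), catalog)
    bind_b = binding_mirnas(build_allele_window(snp, "b"), catalog)
    return RegulationChange(snp.snp_id, gained=frozenset(bind_b - bind_a), lost=frozenset(bind_a - bind_b))


def classify_all(
    snps: Iterable[SnpRecord], catalog: SeedCatalog
) -> tuple[list[RegulationChange], pd.DataFrame]:
    """Classify every SNP; also summarise counts and changed fractions per class.

    Returns the per-SNP verdicts in input order plus a summary frame indexed
    by snp_class (with an ``all`` row) carrying columns ``n``, ``n_changed``
    and ``fraction_changed`` (NaN when a class is empty).
    """
    snps = list(snps)
    ids = [s.snp_id for s in snps]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise DuplicateIdentifierError(f"duplicate snp_ids: {dupes}")
    changes = [classify_snp(s, catalog) for s in snps]

    rows = {}
    for cls in ("synonymous", "nonsynonymous", "all"):
        members = [
            c for s, c in zip(snps, changes) if cls == "all" or s.snp_class == cls
        ]
        n = len(members)
        n_changed = sum(c.changed for c in members)
        rows[cls] = {
            "n": n,
            "n_changed": n_changed,
            "fraction_changed": (n_changed / n) if n else float("nan"),
        }
    summary = pd.DataFrame.from_dict(rows, orient="index")
    summary.index.name = "snp_class"
    return changes, summary


def changed_flags(changes: Iterable[RegulationChange]) -> dict[str, int]:
    """Binary changed/unchanged flags keyed by snp_id, for enrichment tables."""
    return {c.snp_id: int(c.changed) for c in changes}
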