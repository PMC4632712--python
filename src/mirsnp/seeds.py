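"""Canonical miRNA seed-match detection in short nucleotide windows.

A mature miRNA recognises its target principally through its *seed*,
nucleotides 2-8 counted from the 5' end. A target site is a stretch of the
mRNA (sense strand) that is Watson-Crick complementary to the seed, with
four canonical flavours distinguished by whether miRNA position 8 is also
paired and whether the target carries an adenine opposite miRNA position 1:

========  ======================================================  ======
type      target pattern (5'->3' on the mRNA)                     length
========  ======================================================  ======
6mer      revcomp(miRNA 2-7)                                      6
7mer-A1   revcomp(miRNA 2-7) + 'A'                                7
7mer-m8   revcomp(miRNA 2-8)                                      7
8mer-1a   revcomp(miRNA 2-8) + 'A'                                8
========  ======================================================  ======

Matching is literal (no G:U wobble) and only on the given strand. When the
longer site types co-occur at one locus with their nested shorter variants,
only the highest-priority type (8mer-1a > 7mer-m8 > 7mer-A1 > 6mer) among
the counted ones is reported for that (miRNA, locus).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .errors import (
    DuplicateIdentifierError,
    InvalidMiRNAError,
    MalformedSequenceError,
)

#: Site types in decreasing priority.
SITE_PRIORITY: tuple[str, ...] = ("8mer-1a", "7mer-m8", "7mer-A1", "6mer")

#: Span length of each site type on the target.
SITE_LENGTHS: dict[str, int] = {"6mer": 6, "7mer-A1": 7, "7mer-m8": 7, "8mer-1a": 8}

#: Default counted types: the canonical "strong" sites, excluding marginal 6mers.
DEFAULT_COUNTED_TYPES: frozenset[str] = frozenset({"8mer-1a", "7mer-m8", "7mer-A1"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_CHARS = frozenset("ACGTN")


def normalize_sequence(seq: str) -> str:
    """Uppercase a nucleotide string and map RNA U to DNA T.

    Characters outside {A, C, G, T, U, N} (case-insensitive) raise
    :class:`MalformedSequenceError` naming the offending position.
    """
    out = seq.upper().replace("U", "T")
    for i, ch in enumerate(out):
        if ch not in _VALID_CHARS:
            raise MalformedSequenceError(seq, i)
    return out


def reverse_complement(seq: str) -> str:
    """Reverse complement of a normalized (ACGTN) sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MiRNARecord:
    """A mature miRNA: a unique name and its 5'->3' sequence (>= 8 nt).

    The sequence is normalized (U -> T, uppercased) on construction; its
    seed heptamer is positions 2-8 (1-based), i.e. ``mature_seq[1:8]``.
    """

    name: str
    mature_seq: str

    def __post_init__(self) -> None:
        norm = normalize_sequence(self.mature_seq)
        if "N" in norm:
            raise InvalidMiRNAError(f"{self.name}: mature sequence contains N")
        if len(norm) < 8:
            raise InvalidMiRNAError(
                f"{self.name}: mature sequence has {len(norm)} nt, need >= 8"
            )
        object.__setattr__(self, "mature_seq", norm)

    @property
    def seed(self) -> str:
        """Seed heptamer, miRNA positions 2-8."""
        return self.mature_seq[1:8]


@dataclass(frozen=True)
class TargetSite:
    """One located seed-match site, 0-based half-open on the scanned window."""

    mirna_name: str
    site_type: str
    start: int
    end: int


@dataclass(frozen=True)
class SeedCatalog:
    """A collection of miRNAs plus the site types counted as regulation."""

    records: tuple[MiRNARecord, ...]
    counted_types: frozenset[str] = DEFAULT_COUNTED_TYPES

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        object.__setattr__(self, "counted_types", frozenset(self.counted_types))
        names = [m.name for m in self.records]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise DuplicateIdentifierError(f"duplicate miRNA names: {dupes}")
        if not self.counted_types:
            raise ValueError("counted_types must be non-empty")
        unknown = self.counted_types - set(SITE_PRIORITY)
        if unknown:
            raise ValueError(f"unknown site types: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.records)


def seed_match_site(mirna: MiRNARecord) -> dict[str, str]:
    """Target-strand pattern for each canonical site type of one miRNA.

    Returns a mapping site_type -> the exact mRNA subsequence whose presence
    constitutes a match of that type.
    """
    core = reverse_complement(mirna.mature_seq[1:7])  # seed positions 2-7
    extended = reverse_complement(mirna.mature_seq[1:8])  # seed positions 2-8
    return {
        "6mer": core,
        "7mer-m8": extended,
        "7mer-A1": core + "A",
        "8mer-1a": extended + "A",
    }


def _sites_for_mirna(window: str, mirna: MiRNARecord, counted: frozenset[str]):
    patterns = seed_match_site(mirna)
    core = patterns["6mer"]
    m8_base = patterns["7mer-m8"][0]  # target base pairing miRNA position 8
    n = len(window)
    pos = window.find(core)
    while pos != -1:
        has_m8 = pos >= 1 and window[pos - 1] == m8_base
        has_a1 = pos + 6 < n and window[pos + 6] == "A"
        present = {"6mer"}
        if has_m8:
            present.add("7mer-m8")
        if has_a1:
            present.add("7mer-A1")
        if has_m8 and has_a1:
            present.add("8mer-1a")
        for site_type in SITE_PRIORITY:
            if site_type in present and site_type in counted:
                if site_type == "8mer-1a":
                    span = (pos - 1, pos + 7)
                elif site_type == "7mer-m8":
                    span = (pos - 1, pos + 6)
                elif site_type == "7mer-A1":
                    span = (pos, pos + 7)
                else:
                    span = (pos, pos + 6)
                yield TargetSite(mirna.name, site_type, span[0], span[1])
                break
        pos = window.find(core, pos + 1)


def scan_sites(window: str, catalog: SeedCatalog) -> list[TargetSite]:
    """All counted seed-match sites of every catalog miRNA in ``window``.

    The window must be a normalized ACGTN string (``N`` positions never
    match). For each (miRNA, locus) only the highest-priority counted site
    type is reported; output is ordered by (start, mirna_name, site_type).
    """
    window = normalize_sequence(window)
    sites: list[TargetSite] = []
    for mirna in catalog.records:
        sites.extend(_sites_for_mirna(window, mirna, catalog.counted_types))
    sites.sort(key=lambda s: (s.start, s.mirna_name, s.site_type))
    return sites


def binding_mirnas(window: str, catalog: SeedCatalog) -> set[str]:
    """Names of the distinct miRNAs with at least one counted site in ``window``."""
    return {site.mirna_name for site in scan_sites(window, catalog)}


def make_catalog(
    named_seqs: Iterable[tuple[str, str]],
    counted_types: Iterable[str] = DEFAULT_COUNTED_TYPES,
) -> SeedCatalog:
    """Build a :class:`SeedCatalog` from (name, mature_sequence) pairs."""
    records = tuple(MiRNARecord(name, seq) for name, seq in named_seqs)
    return SeedCatalog(records, frozenset(counted_types))
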