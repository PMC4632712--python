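"""2x2 enrichment statistics: Fisher's exact test, odds ratios, the |iHS|
positive-selection screen, and the Wilcoxon rank-sum comparison of score
distributions.

The contingency-table layout throughout is

              annotated   not annotated
    changed       a             b
    unchanged     c             d

so the sample odds ratio is a*d/(b*c); an OR above 1 means SNPs that change
miRNA regulation are over-represented in the annotated set. p-values are
nominal — no multiple-testing adjustment is applied anywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import numpy as np
from scipy import stats

from .errors import (
    EmptySampleError,
    EmptyUniverseError,
    InvalidThresholdError,
)
from .swap import RegulationChange, changed_flags

Alternative = Literal["two-sided", "greater", "less"]

#: |iHS| at or above this marks strong recent positive selection.
DEFAULT_IHS_THRESHOLD = 2.5


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b, c, d): rows changed/unchanged, columns annotated/not."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name}={v!r} must be a non-negative integer")
        if self.total == 0:
            raise EmptyUniverseError("contingency table has zero total")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)

    def has_zero_margin(self) -> bool:
        return 0 in (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


@dataclass(frozen=True)
class EnrichmentResult:
    """A 2x2 table together with its odds ratio and test p-value."""

    table: ContingencyTable2x2
    odds_ratio: float  # may be inf; nan flags the undefined 0/0 case
    p_value: float
    method: str = "fisher"
    alternative: Alternative = "two-sided"
    mode: str | None = None
    population: str | None = None
    degenerate: bool = False


@dataclass(frozen=True)
class AnnotationTrack:
    """Per-SNP labels: a scalar score (iHS) or a binary flag (disease, deleterious).

    Scalar tracks may be partial — SNPs without a score simply have no entry.
    """

    kind: Literal["scalar", "binary"]
    values: Mapping[str, float]
    population: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("scalar", "binary"):
            raise ValueError(f"bad track kind {self.kind!r}")
        object.__setattr__(self, "values", dict(self.values))
        if self.kind == "binary":
            bad = {k: v for k, v in self.values.items() if v not in (0, 1)}
            if bad:
                raise ValueError(f"binary track has non-0/1 values: {list(bad)[:5]}")


def strong_selection_flags(
    track: AnnotationTrack, threshold: float = DEFAULT_IHS_THRESHOLD
) -> dict[str, int]:
    """Flag SNPs with |score| >= threshold; SNPs lacking a score are omitted."""
    if track.kind != "scalar":
        raise ValueError("strong_selection_flags needs a scalar track")
    if threshold <= 0:
        raise InvalidThresholdError(f"threshold must be > 0, got {threshold}")
    return {snp: int(abs(v) >= threshold) for snp, v in track.values.items()}


def make_table(
    changed: Mapping[str, int], annotated: Mapping[str, int]
) -> ContingencyTable2x2:
    """Tally the 2x2 table over the SNPs present in both flag maps."""
    universe = changed.keys() & annotated.keys()
    if not universe:
        raise EmptyUniverseError("changed and annotated flags share no SNPs")
    a = b = c = d = 0
    for snp in universe:
        if changed[snp]:
            if annotated[snp]:
                a += 1
            else:
                b += 1
        elif annotated[snp]:
            c += 1
        else:
            d += 1
    return ContingencyTable2x2(a, b, c, d)


def odds_ratio(table: ContingencyTable2x2) -> float:
    """Sample odds ratio a*d/(b*c); inf for a zero denominator with non-zero
    numerator, nan when both products are zero (undefined)."""
    num = table.a * table.d
    den = table.b * table.c
    if den == 0:
        return math.inf if num > 0 else math.nan
    return num / den


def fisher_exact(
    table: ContingencyTable2x2, alternative: Alternative = "two-sided"
) -> float:
    """Fisher's exact test p-value for the 2x2 table.

    Two-sided p follows the probability-mass convention (the sum of
    hypergeometric probabilities of all tables with fixed margins whose
    point probability does not exceed the observed one), matching R's
    ``fisher.test``. A zero margin makes the table degenerate; p = 1 then.
    """
    if table.has_zero_margin():
        return 1.0
    _, p = stats.fisher_exact(table.as_array(), alternative=alternative)
    return float(min(p, 1.0))


def wilcoxon_rank_sum(
    xs: Iterable[float], ys: Iterable[float], alternative: Alternative = "two-sided"
) -> float:
    """Wilcoxon rank-sum (Mann-Whitney) p-value comparing two samples.

    Uses the exact null distribution when both samples have <= 50
    observations and no ties straddle them; otherwise the normal
    approximation with continuity and tie correction.
    """
    xs = np.asarray(list(xs), dtype=float)
    ys = np.asarray(list(ys), dtype=float)
    if xs.size == 0 or ys.size == 0:
        raise EmptySampleError("wilcoxon_rank_sum requires two non-empty samples")
    combined = np.concatenate([xs, ys])
    has_ties = np.unique(combined).size < combined.size
    small = max(xs.size, ys.size) <= 50
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        xs, ys, alternative=alternative, method=method, use_continuity=True
    )
    return float(res.pvalue)


def run_enrichment(
    changes: Iterable[RegulationChange],
    track: AnnotationTrack,
    mode: Literal["selection", "disease"],
    ihs_threshold: float = DEFAULT_IHS_THRESHOLD,
    alternative: Alternative = "two-sided",
) -> EnrichmentResult:
    """Fisher enrichment of regulation-changing SNPs in an annotation track.

    ``selection`` mode thresholds a scalar |iHS| track (SNPs without a score
    drop out of the universe); ``disease`` mode uses a binary track as-is.
    """
    changed = changed_flags(changes)
    if mode == "selection":
        annotated = strong_selection_flags(track, ihs_threshold)
    elif mode == "disease":
        if track.kind != "binary":
            raise ValueError("disease mode needs a binary track")
        annotated = {k: int(v) for k, v in track.values.items()}
    else:
        raise ValueError(f"unknown mode {mode!r}")
    table = make_table(changed, annotated)
    degenerate = table.has_zero_margin()
    return EnrichmentResult(
        table=table,
        odds_ratio=odds_ratio(table),
        p_value=fisher_exact(table, alternative),
        method="fisher",
        alternative=alternative,
        mode=mode,
        population=track.population,
        degenerate=degenerate,
    )
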