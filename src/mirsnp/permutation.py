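"""Empirical permutation null for SNP-set overlap counts.

How many regulation-changing SNPs fall into an annotated set (e.g. SNPs
under strong recent positive selection), compared with random draws of the
same number of SNPs from the universe? Each permutation draws
|changed_set| identifiers uniformly without replacement, so the null count
is Hypergeometric(|universe|, |annotated|, |changed|); the empirical
distribution is kept so the familiar null histogram can be plotted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

from .errors import InconsistentInputError

DEFAULT_N_PERM = 10_000
MIN_N_PERM = 100


@dataclass(frozen=True)
class PermutationResult:
    """Observed overlap, its permutation null, and the empirical p-value."""

    observed: int
    expected: float
    null_counts: np.ndarray
    p_value: float
    n_perm: int
    seed: int
    alternative: str = "greater"

    def __post_init__(self) -> None:
        counts = np.asarray(self.null_counts, dtype=np.int64)
        counts.setflags(write=False)
        object.__setattr__(self, "null_counts", counts)


def permute_overlap(
    universe: Iterable[str],
    changed_set: Iterable[str],
    annotated_set: Iterable[str],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    alternative: Literal["greater", "less", "two-sided"] = "greater",
) -> PermutationResult:
    """Permutation test for the overlap |changed_set & annotated_set|.

    The +1-corrected empirical p-value is used, so p is never below
    1/(n_perm+1). ``alternative='greater'`` (default) asks whether the
    observed overlap is higher than expected by chance; the two-sided
    variant doubles the smaller tail.
    """
    universe = sorted(set(universe))
    changed = set(changed_set)
    annotated = set(annotated_set)
    uni = set(universe)
    if not changed <= uni or not annotated <= uni:
        stray = sorted((changed | annotated) - uni)[:5]
        raise InconsistentInputError(
            f"changed/annotated sets are not subsets of the universe (e.g. {stray})"
        )
    if n_perm < MIN_N_PERM:
        raise ValueError(f"n_perm must be >= {MIN_N_PERM}, got {n_perm}")

    n = len(universe)
    k = len(changed)
    annotated_mask = np.fromiter(
        (snp in annotated for snp in universe), dtype=bool, count=n
    )
    rng = np.random.default_rng(seed)
    null_counts = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        idx = rng.choice(n, size=k, replace=False)
        null_counts[i] = int(annotated_mask[idx].sum())

    observed = len(changed & annotated)
    upper = (int(np.sum(null_counts >= observed)) + 1) / (n_perm + 1)
    lower = (int(np.sum(null_counts <= observed)) + 1) / (n_perm + 1)
    if alternative == "greater":
        p = upper
    elif alternative == "less":
        p = lower
    elif alternative == "two-sided":
        p = min(1.0, 2.0 * min(upper, lower))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")

    return PermutationResult(
        observed=observed,
        expected=float(null_counts.mean()),
        null_counts=null_counts,
        p_value=float(p),
        n_perm=n_perm,
        seed=seed,
        alternative=alternative,
    )


def null_histogram(result: PermutationResult) -> "np.ndarray":
    """(count, frequency) pairs of the null distribution, for plotting."""
    values, freqs = np.unique(result.null_counts, return_counts=True)
    return np.column_stack([values, freqs])
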