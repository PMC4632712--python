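"""Genotype-expression association and its gene-level enrichment.

Each SNP's genotypes (alternate-allele dosage 0/1/2) are tested against the
expression of its host gene by Spearman rank correlation, missing genotypes
dropped pairwise. At the gene level, genes are split by whether they host
at least one regulation-changing SNP, a gene counts as *significant* when
any of its SNP associations reaches the nominal alpha, and the resulting
2x2 table goes through the same Fisher/odds-ratio machinery as every other
enrichment. This any-SNP aggregation with an unadjusted alpha is
deliberately anti-conservative; it mirrors how host-gene eQTL preference is
usually screened, not how eQTL discovery is done.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import (
    Alternative,
    ContingencyTable2x2,
    EnrichmentResult,
    fisher_exact,
    odds_ratio,
)
from .errors import InsufficientDataError, MissingMappingError
from .swap import RegulationChange

DEFAULT_ALPHA = 0.05

#: Below this sample count the Spearman p comes from exact permutation.
EXACT_PERMUTATION_MAX_N = 9


@dataclass(frozen=True)
class GenotypeMatrix:
    """SNP x sample alternate-allele dosages (0/1/2, NaN = missing)."""

    data: pd.DataFrame  # index snp_ids, columns sample_ids

    def __post_init__(self) -> None:
        values = self.data.to_numpy(dtype=float)
        ok = np.isnan(values) | np.isin(values, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("genotypes must be 0, 1, 2 or missing")

    @property
    def snp_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene x sample expression values."""

    data: pd.DataFrame  # index gene_ids, columns sample_ids

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass(frozen=True)
class AssocResult:
    """One SNP-gene Spearman association; testable=False marks monomorphic SNPs."""

    snp_id: str
    gene_id: str
    rho: float
    p_value: float
    n_used: int
    testable: bool = True


def _rank(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    return float(xc @ yc) / denom if denom > 0 else math.nan


def _exact_spearman_p(gr: np.ndarray, er: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact p by enumerating every pairing of the two rank vectors."""
    n = gr.size
    perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
    permuted = er[perms]  # (n!, n)
    xc = gr - gr.mean()
    yc = permuted - permuted.mean(axis=1, keepdims=True)
    denom = np.sqrt(float(xc @ xc) * (yc * yc).sum(axis=1))
    rhos = (yc @ xc) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman_assoc(
    genotypes: Iterable[float], expression: Iterable[float]
) -> tuple[float, float, int]:
    """Spearman rho, two-sided p and the sample count actually used.

    Pairs with a missing value on either side are dropped. Ties get average
    ranks. For n < 10 the p-value is exact (all pairings enumerated);
    otherwise the usual t-approximation is used. A monomorphic genotype
    vector yields (nan, nan, n) — flagged untestable upstream.
    """
    g = np.asarray(list(genotypes), dtype=float)
    e = np.asarray(list(expression), dtype=float)
    if g.shape != e.shape:
        raise ValueError("genotype and expression vectors differ in length")
    keep = ~(np.isnan(g) | np.isnan(e))
    g, e = g[keep], e[keep]
    n = int(g.size)
    if n < 3:
        raise InsufficientDataError(f"only {n} shared non-missing samples, need >= 3")
    if np.unique(g).size < 2 or np.unique(e).size < 2:
        return math.nan, math.nan, n
    gr, er = _rank(g), _rank(e)
    rho = _pearson(gr, er)
    if n <= EXACT_PERMUTATION_MAX_N:
        p = _exact_spearman_p(gr, er, rho)
    else:
        p = float(stats.spearmanr(g, e).pvalue)
    return rho, p, n


def associate(
    genotypes: GenotypeMatrix,
    expression: ExpressionMatrix,
    snp_to_gene: Mapping[str, str],
) -> list[AssocResult]:
    """Spearman association of every SNP with its mapped gene's expression.

    SNPs absent from the mapping raise; SNPs mapped to genes without
    expression data are skipped. Samples are aligned by shared identifiers.
    """
    unmapped = [s for s in genotypes.snp_ids if s not in snp_to_gene]
    if unmapped:
        raise MissingMappingError(unmapped)
    shared = [s for s in genotypes.sample_ids if s in set(expression.sample_ids)]
    if len(shared) < 3:
        raise InsufficientDataError(
            f"only {len(shared)} samples shared between matrices"
        )
    gdat = genotypes.data[shared]
    edat = expression.data[shared]
    results: list[AssocResult] = []
    for snp_id in genotypes.snp_ids:
        gene_id = snp_to_gene[snp_id]
        if gene_id not in edat.index:
            continue
        rho, p, n = spearman_assoc(gdat.loc[snp_id], edat.loc[gene_id])
        results.append(
            AssocResult(snp_id, gene_id, rho, p, n, testable=not math.isnan(rho))
        )
    return results


def gene_level_enrichment(
    assoc: Iterable[AssocResult],
    changes: Iterable[RegulationChange],
    snp_to_gene: Mapping[str, str],
    alpha: float = DEFAULT_ALPHA,
    alternative: Alternative = "two-sided",
) -> EnrichmentResult:
    """Do genes hosting regulation-changing SNPs prefer to show eQTL signal?

    Gene universe = all genes in the mapping. A gene is *changed* when it
    hosts >= 1 changing SNP and *significant* when any of its testable SNP
    associations has p <= alpha.
    """
    assoc = list(assoc)
    unmapped = {r.snp_id for r in assoc if r.snp_id not in snp_to_gene}
    if unmapped:
        raise MissingMappingError(unmapped)
    genes = set(snp_to_gene.values())
    changed_genes = {
        snp_to_gene[c.snp_id]
        for c in changes
        if c.changed and c.snp_id in snp_to_gene
    }
    significant_genes = {
        r.gene_id for r in assoc if r.testable and r.p_value <= alpha
    }
    a = len(changed_genes & significant_genes)
    b = len(changed_genes - significant_genes)
    c = len(significant_genes - changed_genes)
    d = len(genes - changed_genes - significant_genes)
    table = ContingencyTable2x2(a, b, c, d)
    return EnrichmentResult(
        table=table,
        odds_ratio=odds_ratio(table),
        p_value=fisher_exact(table, alternative),
        method="fisher",
        alternative=alternative,
        mode="expression",
        degenerate=table.has_zero_margin(),
    )


def assoc_frame(results: Iterable[AssocResult]) -> pd.DataFrame:
    """Tabulate association results for output."""
    return pd.DataFrame(
        [
            {
                "snp_id": r.snp_id,
                "gene_id": r.gene_id,
                "rho": r.rho,
                "p_value": r.p_value,
                "n_used": r.n_used,
                "testable": int(r.testable),
            }
            for r in results
        ]
    )
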