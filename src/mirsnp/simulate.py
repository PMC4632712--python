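"""Synthetic inputs with the statistical structure every pipeline stage assumes.

The generators emulate, at desk scale, the shape of the genome-wide inputs
the analysis was designed for: a catalog of mature miRNAs; coding-region
SNPs a known fraction of which flip a canonical seed-match site overlapping
the variant base (truth labels are returned, and the flip is *constructed*
and verified against the scanner, not sampled and hoped for); |iHS| scores
per population with a planted location shift for changing SNPs and partial
coverage; binary disease labels with a planted odds ratio; and
Hardy-Weinberg genotypes with expression = beta * dosage + noise for a
planted subset of changing-SNP genes.

Every generator is a pure function of (config, seed): a fixed config gives
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import AnnotationTrack
from .errors import GeneratorExhaustedError
from .expression import ExpressionMatrix, GenotypeMatrix
from .seeds import (
    DEFAULT_COUNTED_TYPES,
    MiRNARecord,
    SeedCatalog,
    binding_mirnas,
    seed_match_site,
)
from .swap import FLANK_LENGTH, SnpRecord

_BASES = np.array(list("ACGT"))
_POPULATIONS = ("ASN", "CEU", "YRI")
_MAX_RETRIES = 200


@dataclass(frozen=True)
class SimulationConfig:
    """Tunable knobs of the synthetic study; defaults mirror the real-data regime.

    change_rate_target is the genome-wide fraction of coding SNPs that alter
    the bound-miRNA set; planted_or_disease the changed-vs-unchanged disease
    odds ratio; planted_ihs_shift the |iHS| location shift added for
    changing SNPs; ihs_tail_frac the null fraction with |iHS| >= 2.5.
    """

    n_snps: int = 5000
    n_mirnas: int = 100
    mirna_length: int = 22
    counted_types: frozenset[str] = DEFAULT_COUNTED_TYPES
    change_rate_target: float = 0.459
    nonsyn_frac: float = 0.5
    planted_or_disease: float = 1.6
    disease_baseline_rate: float = 0.002  # GWAS-catalog-like
    clinvar_baseline_rate: float = 0.07  # ClinVar-like
    deleterious_rate: float = 0.18
    planted_ihs_shift: float = 0.1
    ihs_tail_frac: float = 0.0124  # standard-normal mass beyond |2.5|
    ihs_missing_frac: float = 0.3
    n_samples: int = 60
    maf_range: tuple[float, float] = (0.05, 0.5)
    eqtl_effect_sd: float = 1.0
    eqtl_frac: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_snps", "n_mirnas", "mirna_length", "n_samples"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in (
            "change_rate_target",
            "nonsyn_frac",
            "ihs_tail_frac",
            "ihs_missing_frac",
            "eqtl_frac",
            "disease_baseline_rate",
            "clinvar_baseline_rate",
            "deleterious_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must lie in [0, 1), got {v}")
        if self.planted_or_disease <= 0:
            raise ValueError("planted_or_disease must be positive")
        lo, hi = self.maf_range
        if not 0 < lo <= hi < 1:
            raise ValueError(f"bad maf_range {self.maf_range}")


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    # independent stream per stage so adding a stage never shifts another
    return np.random.default_rng([config.seed, stage])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def simulate_catalog(config: SimulationConfig) -> SeedCatalog:
    """Random mature miRNAs with unique names and unique seed heptamers.

    Seed collisions are re-drawn (two catalog entries with an identical seed
    would be indistinguishable to the scanner), up to a retry budget.
    """
    rng = _rng(config, 1)
    records: list[MiRNARecord] = []
    seen_seeds: set[str] = set()
    for i in range(config.n_mirnas):
        for _ in range(_MAX_RETRIES):
            seq = _random_seq(rng, config.mirna_length)
            rec = MiRNARecord(f"mir-{i:04d}", seq)
            if rec.seed not in seen_seeds:
                seen_seeds.add(rec.seed)
                records.append(rec)
                break
        else:
            raise GeneratorExhaustedError(
                f"could not draw a unique seed for miRNA {i} "
                f"({len(seen_seeds)} of 4^7 heptamers used)"
            )
    return SeedCatalog(tuple(records), config.counted_types)


def _plant_changed_snp(
    rng: np.random.Generator, catalog: SeedCatalog, snp_id: str, snp_class: str
) -> SnpRecord:
    """Construct a SNP whose two windows bind different miRNA sets.

    A counted site pattern is embedded so it overlaps the central base; the
    alternate allele replaces that base, which destroys the match. The
    scanner itself verifies the binding sets differ (the substitution could
    in principle leave a lower-priority counted site, or create one for
    another miRNA that restores equality).
    """
    types = sorted(catalog.counted_types)
    for _ in range(_MAX_RETRIES):
        mirna = catalog.records[rng.integers(len(catalog.records))]
        site_type = types[rng.integers(len(types))]
        pattern = seed_match_site(mirna)[site_type]
        j = int(rng.integers(len(pattern)))  # pattern position landing on the centre
        offset = FLANK_LENGTH - j
        window = list(_random_seq(rng, 2 * FLANK_LENGTH + 1))
        window[offset : offset + len(pattern)] = pattern
        allele_a = window[FLANK_LENGTH]
        window_a = "".join(window)
        others = [b for b in "ACGT" if b != allele_a]
        rng.shuffle(others)
        for allele_b in others:
            window_b = window_a[:FLANK_LENGTH] + allele_b + window_a[FLANK_LENGTH + 1 :]
            if binding_mirnas(window_a, catalog) != binding_mirnas(window_b, catalog):
                return SnpRecord(
                    snp_id,
                    left_flank=window_a[:FLANK_LENGTH],
                    right_flank=window_a[FLANK_LENGTH + 1 :],
                    allele_a=allele_a,
                    allele_b=allele_b,
                    snp_class=snp_class,
                )
    raise GeneratorExhaustedError(f"{snp_id}: could not plant a regulation change")


def _draw_unchanged_snp(
    rng: np.random.Generator, catalog: SeedCatalog, snp_id: str, snp_class: str
) -> SnpRecord:
    """Draw a SNP verified by the scanner to leave the bound set intact."""
    for _ in range(_MAX_RETRIES):
        window_a = _random_seq(rng, 2 * FLANK_LENGTH + 1)
        allele_a = window_a[FLANK_LENGTH]
        others = [b for b in "ACGT" if b != allele_a]
        allele_b = others[rng.integers(3)]
        window_b = window_a[:FLANK_LENGTH] + allele_b + window_a[FLANK_LENGTH + 1 :]
        if binding_mirnas(window_a, catalog) == binding_mirnas(window_b, catalog):
            return SnpRecord(
                snp_id,
                left_flank=window_a[:FLANK_LENGTH],
                right_flank=window_a[FLANK_LENGTH + 1 :],
                allele_a=allele_a,
                allele_b=allele_b,
                snp_class=snp_class,
            )
    raise GeneratorExhaustedError(f"{snp_id}: could not draw an unchanged SNP")


def simulate_snps(
    config: SimulationConfig, catalog: SeedCatalog
) -> tuple[list[SnpRecord], pd.Series]:
    """SNPs with constructed truth labels for "changes miRNA regulation".

    Each SNP is independently changed with probability change_rate_target;
    labels are exact by construction (classify_all must agree 100%).
    Returns the records and a boolean truth Series indexed by snp_id.
    """
    if len(catalog) == 0 and config.n_snps > 0 and config.change_rate_target > 0:
        raise ValueError("cannot plant regulation changes with an empty catalog")
    rng = _rng(config, 2)
    records: list[SnpRecord] = []
    truth: dict[str, bool] = {}
    for i in range(config.n_snps):
        snp_id = f"rs{i:06d}"
        snp_class = (
            "nonsynonymous" if rng.random() < config.nonsyn_frac else "synonymous"
        )
        changed = bool(rng.random() < config.change_rate_target)
        if changed:
            rec = _plant_changed_snp(rng, catalog, snp_id, snp_class)
        else:
            rec = _draw_unchanged_snp(rng, catalog, snp_id, snp_class)
        records.append(rec)
        truth[snp_id] = changed
    return records, pd.Series(truth, name="changed", dtype=bool)


def _planted_binary_flags(
    rng: np.random.Generator,
    truth: pd.Series,
    baseline_rate: float,
    planted_or: float,
) -> dict[str, int]:
    base_logit = math.log(baseline_rate / (1 - baseline_rate))
    p_changed = 1.0 / (1.0 + math.exp(-(base_logit + math.log(planted_or))))
    probs = np.where(truth.to_numpy(), p_changed, baseline_rate)
    flags = (rng.random(len(truth)) < probs).astype(int)
    return dict(zip(truth.index, flags))


def simulate_annotations(
    config: SimulationConfig, truth: pd.Series
) -> dict[str, AnnotationTrack]:
    """Annotation tracks keyed ihs_<POP>, disease_gwas, disease_clinvar, deleterious.

    iHS is Normal(0, s) with s chosen so the null |iHS| >= 2.5 mass equals
    ihs_tail_frac; changing SNPs get planted_ihs_shift added to |iHS|. A
    random ihs_missing_frac of SNPs lacks a score in each population.
    Disease flags carry the planted odds ratio; SIFT-style deleterious flags
    are independent of change status (no planted effect).
    """
    rng = _rng(config, 3)
    n = len(truth)
    snp_ids = truth.index.to_numpy()
    is_changed = truth.to_numpy()
    scale = 2.5 / stats.norm.ppf(1 - config.ihs_tail_frac / 2)

    tracks: dict[str, AnnotationTrack] = {}
    for pop in _POPULATIONS:
        z = rng.normal(0.0, scale, size=n)
        shifted = np.where(
            is_changed, np.sign(z) * (np.abs(z) + config.planted_ihs_shift), z
        )
        present = rng.random(n) >= config.ihs_missing_frac
        values = {
            snp: float(v) for snp, v, keep in zip(snp_ids, shifted, present) if keep
        }
        tracks[f"ihs_{pop}"] = AnnotationTrack("scalar", values, population=pop)

    tracks["disease_gwas"] = AnnotationTrack(
        "binary",
        _planted_binary_flags(
            rng, truth, config.disease_baseline_rate, config.planted_or_disease
        ),
    )
    tracks["disease_clinvar"] = AnnotationTrack(
        "binary",
        _planted_binary_flags(
            rng, truth, config.clinvar_baseline_rate, config.planted_or_disease
        ),
    )
    deleterious = (rng.random(n) < config.deleterious_rate).astype(int)
    tracks["deleterious"] = AnnotationTrack(
        "binary", dict(zip(snp_ids, deleterious))
    )
    return tracks


def simulate_snp_gene_map(
    config: SimulationConfig, snp_ids: Sequence[str]
) -> dict[str, str]:
    """Host-gene relation: consecutive runs of 1-3 SNPs share a gene."""
    rng = _rng(config, 4)
    mapping: dict[str, str] = {}
    gene_idx = 0
    i = 0
    while i < len(snp_ids):
        run = int(rng.integers(1, 4))
        for snp_id in snp_ids[i : i + run]:
            mapping[snp_id] = f"gene{gene_idx:05d}"
        gene_idx += 1
        i += run
    return mapping


def simulate_expression(
    config: SimulationConfig,
    truth: pd.Series,
    snp_to_gene: Mapping[str, str],
) -> tuple[GenotypeMatrix, ExpressionMatrix, dict[str, float]]:
    """Hardy-Weinberg genotypes plus expression with planted eQTL effects.

    An eqtl_frac of genes hosting changing SNPs receives effect
    beta ~ Normal(0, eqtl_effect_sd^2) on the dosage of its first changing
    SNP; every other gene is pure noise. Returns the matrices and the
    planted gene -> beta map (the truth for power checks).
    """
    rng = _rng(config, 5)
    snp_ids = [s for s in truth.index if s in snp_to_gene]
    samples = [f"S{j:03d}" for j in range(config.n_samples)]
    lo, hi = config.maf_range
    mafs = rng.uniform(lo, hi, size=len(snp_ids))
    geno = rng.binomial(2, mafs[:, None], size=(len(snp_ids), config.n_samples))
    gmat = pd.DataFrame(geno.astype(float), index=snp_ids, columns=samples)

    genes: list[str] = sorted(set(snp_to_gene[s] for s in snp_ids))
    first_changed: dict[str, str] = {}
    for snp_id in snp_ids:
        gene = snp_to_gene[snp_id]
        if truth[snp_id] and gene not in first_changed:
            first_changed[gene] = snp_id
    changed_genes = sorted(first_changed)
    planted_mask = rng.random(len(changed_genes)) < config.eqtl_frac
    planted = {
        gene: float(rng.normal(0.0, config.eqtl_effect_sd))
        for gene, keep in zip(changed_genes, planted_mask)
        if keep
    }

    expr = rng.normal(0.0, 1.0, size=(len(genes), config.n_samples))
    emat = pd.DataFrame(expr, index=genes, columns=samples)
    for gene, beta in planted.items():
        emat.loc[gene] += beta * gmat.loc[first_changed[gene]].to_numpy()
    return GenotypeMatrix(gmat), ExpressionMatrix(emat), planted


@dataclass(frozen=True)
class SimulatedBundle:
    """Everything one pipeline run needs, plus the planted truth."""

    config: SimulationConfig
    catalog: SeedCatalog
    snps: list[SnpRecord]
    truth: pd.Series
    tracks: dict[str, AnnotationTrack]
    snp_to_gene: dict[str, str]
    genotypes: GenotypeMatrix
    expression: ExpressionMatrix
    planted_eqtl: dict[str, float]


def simulate_bundle(config: SimulationConfig) -> SimulatedBundle:
    """Generate the full synthetic input bundle for an end-to-end run."""
    catalog = simulate_catalog(config)
    snps, truth = simulate_snps(config, catalog)
    tracks = simulate_annotations(config, truth)
    snp_to_gene = simulate_snp_gene_map(config, list(truth.index))
    genotypes, expression, planted = simulate_expression(config, truth, snp_to_gene)
    return SimulatedBundle(
        config=config,
        catalog=catalog,
        snps=snps,
        truth=truth,
        tracks=tracks,
        snp_to_gene=snp_to_gene,
        genotypes=genotypes,
        expression=expression,
        planted_eqtl=planted,
    )
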