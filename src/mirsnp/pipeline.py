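"""End-to-end orchestration: classify -> enrich -> randomize -> expression.

A :class:`PipelineConfig` names every input file plus the analysis knobs
(counted site types, |iHS| threshold, alpha, permutation count, seed);
:func:`run_pipeline` executes the stages and writes one machine-readable
summary containing every table, odds ratio, p-value and seed, so each
result can be re-derived without hidden state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .enrichment import (
    DEFAULT_IHS_THRESHOLD,
    run_enrichment,
    wilcoxon_rank_sum,
)
from .errors import MirsnpError
from .expression import DEFAULT_ALPHA, associate, gene_level_enrichment
from .io import (
    enrichment_row,
    read_expression_matrix,
    read_genotype_matrix,
    read_mirna_catalog,
    read_snp_gene_map,
    read_snps,
    read_track,
    write_assoc_results,
    write_changes,
    write_enrichment_results,
    write_permutation_result,
    write_summary_json,
)
from .permutation import DEFAULT_N_PERM, permute_overlap
from .seeds import DEFAULT_COUNTED_TYPES
from .swap import changed_flags, classify_all

logger = logging.getLogger("mirsnp")


@dataclass
class PipelineConfig:
    """Paths and knobs for one full analysis run.

    ``ihs_tracks`` maps population -> scalar track TSV; ``disease_tracks``
    maps label -> binary track TSV. Expression inputs are optional — the
    stage is skipped when any of the three paths is missing.
    """

    catalog_path: str
    snps_path: str
    out_dir: str
    snp_dialect: str = "tsv"
    fasta_path: str | None = None
    cds_bed_path: str | None = None
    ihs_tracks: dict[str, str] = field(default_factory=dict)
    disease_tracks: dict[str, str] = field(default_factory=dict)
    genotypes_path: str | None = None
    expression_path: str | None = None
    snp_gene_map_path: str | None = None
    counted_types: list[str] = field(default_factory=lambda: sorted(DEFAULT_COUNTED_TYPES))
    ihs_threshold: float = DEFAULT_IHS_THRESHOLD
    alpha: float = DEFAULT_ALPHA
    n_perm: int = DEFAULT_N_PERM
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _stage(name: str):
    logger.info("stage: %s", name)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; write per-stage TSVs and a summary JSON.

    Returns the summary dict. Any stage failure is re-raised with the stage
    name prefixed so the culprit is unambiguous.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "counted_types": sorted(config.counted_types),
        "ihs_threshold": config.ihs_threshold,
        "alpha": config.alpha,
        "n_perm": config.n_perm,
    }
    logger.info(
        "counted site types: %s; |iHS| threshold %.2f; alpha %.2f",
        ",".join(sorted(config.counted_types)),
        config.ihs_threshold,
        config.alpha,
    )

    stage = "classify"
    try:
        _stage(stage)
        catalog = read_mirna_catalog(config.catalog_path, config.counted_types)
        snps = read_snps(
            config.snps_path,
            dialect=config.snp_dialect,  # type: ignore[arg-type]
            fasta_path=config.fasta_path,
            cds_bed_path=config.cds_bed_path,
        )
        changes, class_summary = classify_all(snps, catalog)
        write_changes(changes, out / "changes.tsv")
        summary["classification"] = {
            cls: {
                "n": int(row["n"]),
                "n_changed": int(row["n_changed"]),
                "fraction_changed": (
                    None if row["n"] == 0 else float(row["fraction_changed"])
                ),
            }
            for cls, row in class_summary.iterrows()
        }
        flags = changed_flags(changes)

        stage = "enrichment"
        _stage(stage)
        enrichments = []
        for pop, path in sorted(config.ihs_tracks.items()):
            track = read_track(path, "scalar", population=pop)
            result = run_enrichment(
                changes, track, "selection", ihs_threshold=config.ihs_threshold
            )
            enrichments.append(result)
            values = track.values
            xs = [abs(values[c.snp_id]) for c in changes if c.changed and c.snp_id in values]
            ys = [abs(values[c.snp_id]) for c in changes if not c.changed and c.snp_id in values]
            wilcoxon_p = (
                wilcoxon_rank_sum(xs, ys) if xs and ys else None
            )
            summary.setdefault("selection", {})[pop] = {
                **enrichment_row(result),
                "wilcoxon_abs_ihs_p": wilcoxon_p,
            }
        for label, path in sorted(config.disease_tracks.items()):
            track = read_track(path, "binary")
            result = run_enrichment(changes, track, "disease")
            enrichments.append(result)
            summary.setdefault("disease", {})[label] = enrichment_row(result)
        if enrichments:
            write_enrichment_results(enrichments, out / "enrichment.tsv")

        stage = "randomization"
        _stage(stage)
        summary["randomization"] = {}
        for label, path in sorted(config.disease_tracks.items()):
            track = read_track(path, "binary")
            universe = flags.keys() & track.values.keys()
            changed_set = {s for s in universe if flags[s]}
            annotated_set = {s for s in universe if track.values[s]}
            perm = permute_overlap(
                universe,
                changed_set,
                annotated_set,
                n_perm=config.n_perm,
                seed=config.seed,
            )
            write_permutation_result(
                perm,
                out / f"randomization_{label}.tsv",
                out / f"randomization_{label}_hist.tsv",
            )
            summary["randomization"][label] = {
                "observed": perm.observed,
                "expected": perm.expected,
                "p_value": perm.p_value,
                "n_perm": perm.n_perm,
                "seed": perm.seed,
            }

        stage = "expression"
        if (
            config.genotypes_path
            and config.expression_path
            and config.snp_gene_map_path
        ):
            _stage(stage)
            genotypes = read_genotype_matrix(config.genotypes_path)
            expression = read_expression_matrix(config.expression_path)
            snp_to_gene = read_snp_gene_map(config.snp_gene_map_path)
            assoc = associate(genotypes, expression, snp_to_gene)
            write_assoc_results(assoc, out / "assoc.tsv")
            gene_result = gene_level_enrichment(
                assoc, changes, snp_to_gene, alpha=config.alpha
            )
            summary["expression"] = {
                **enrichment_row(gene_result),
                "n_assoc": len(assoc),
                "n_testable": sum(r.testable for r in assoc),
            }
    except MirsnpError as exc:
        raise MirsnpError(f"pipeline stage {stage!r} failed: {exc}") from exc

    write_summary_json(summary, out / "summary.json")
    return summary
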