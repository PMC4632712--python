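"""Readers and writers for the pipeline's file formats.

miRNA catalogs come as FASTA (record id = name) or two-column TSV; SNPs as
a self-contained TSV (dialect A: snp_id, left_flank, ref, alt, right_flank,
snp_class) or as a minimal VCF plus reference FASTA plus a CDS BED with
strand (dialect B), in which case flanks are extracted on the mRNA sense
strand — minus-strand records are reverse-complemented at this boundary so
downstream modules always see sense-strand sequence. VCF coordinates are
1-based per the standard and converted to 0-based here. Multi-allelic VCF
rows are split into per-alternate biallelic records.

All tabular outputs are TSV; write-then-read round-trips reproduce the
in-memory values exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .enrichment import AnnotationTrack, EnrichmentResult
from .errors import MirsnpError
from .expression import AssocResult, ExpressionMatrix, GenotypeMatrix, assoc_frame
from .permutation import PermutationResult, null_histogram
from .seeds import (
    DEFAULT_COUNTED_TYPES,
    SeedCatalog,
    TargetSite,
    make_catalog,
    normalize_sequence,
    reverse_complement,
)
from .swap import FLANK_LENGTH, RegulationChange, SnpRecord


class ParseError(MirsnpError):
    """A file violated its expected format; message names file and line."""


# ---------------------------------------------------------------- catalogs


def read_mirna_catalog(
    path: str | Path,
    counted_types: Iterable[str] = DEFAULT_COUNTED_TYPES,
) -> SeedCatalog:
    """Load a miRNA catalog from FASTA or name/sequence TSV (sniffed)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith(">"):
        pairs = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")]
    else:
        frame = pd.read_csv(path, sep="\t", dtype=str)
        want = {"name", "mature_seq"}
        if not want <= set(frame.columns):
            raise ParseError(f"{path}: need columns {sorted(want)}, got {list(frame.columns)}")
        pairs = list(zip(frame["name"], frame["mature_seq"]))
    return make_catalog(pairs, counted_types)


def write_mirna_catalog(catalog: SeedCatalog, path: str | Path) -> None:
    frame = pd.DataFrame(
        [(m.name, m.mature_seq) for m in catalog.records],
        columns=["name", "mature_seq"],
    )
    frame.to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------- SNPs

_SNP_COLUMNS = ["snp_id", "left_flank", "ref", "alt", "right_flank", "snp_class"]


def read_snps_tsv(path: str | Path) -> list[SnpRecord]:
    """Dialect A: self-contained SNP TSV with flanks already on the sense strand."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_SNP_COLUMNS) - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for lineno, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            records.append(
                SnpRecord(
                    snp_id=row.snp_id,
                    left_flank=row.left_flank,
                    right_flank=row.right_flank,
                    allele_a=row.ref,
                    allele_b=row.alt,
                    snp_class=row.snp_class,
                )
            )
        except (ValueError, MirsnpError) as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_snps_tsv(snps: Iterable[SnpRecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            (s.snp_id, s.left_flank, s.allele_a, s.allele_b, s.right_flank, s.snp_class)
            for s in snps
        ],
        columns=_SNP_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False)


def _read_cds_bed(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
        dtype={"chrom": str, "start": int, "end": int, "name": str, "strand": str},
    )
    bad = ~frame["strand"].isin(["+", "-"])
    if bad.any():
        raise ParseError(f"{path}: strand must be + or - (line {bad.idxmax() + 1})")
    return frame


def read_snps_vcf(
    vcf_path: str | Path,
    fasta_path: str | Path,
    cds_bed_path: str | Path,
    class_info_key: str = "CLASS",
) -> list[SnpRecord]:
    """Dialect B: minimal VCF + reference FASTA + stranded CDS BED.

    Flanks are the 15 reference bases each side of POS clipped to the
    enclosing CDS interval; on minus-strand intervals flanks and alleles
    are reverse-complemented so the record is sense-strand. Records outside
    every CDS interval are skipped; multi-allelic rows are split. The
    synonymous/nonsynonymous class is read from INFO ``CLASS`` when present
    (default synonymous, since the VCF columns cannot encode it).
    """
    import pysam
    from pyfaidx import Fasta

    bed = _read_cds_bed(cds_bed_path)
    ref = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    records: list[SnpRecord] = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            pos0 = rec.pos - 1  # VCF is 1-based
            hits = bed[
                (bed["chrom"] == rec.chrom)
                & (bed["start"] <= pos0)
                & (pos0 < bed["end"])
            ]
            if hits.empty:
                continue
            interval = hits.iloc[0]
            if len(rec.ref) != 1:
                continue  # not a SNP
            snp_class = "synonymous"
            if class_info_key in rec.info:
                value = rec.info[class_info_key]
                snp_class = value[0] if isinstance(value, tuple) else str(value)
            left_lo = max(int(interval["start"]), pos0 - FLANK_LENGTH)
            right_hi = min(int(interval["end"]), pos0 + 1 + FLANK_LENGTH)
            left = normalize_sequence(ref[rec.chrom][left_lo:pos0])
            right = normalize_sequence(ref[rec.chrom][pos0 + 1 : right_hi])
            for alt_idx, alt in enumerate(rec.alts or ()):
                if len(alt) != 1 or alt not in "ACGT":
                    continue
                snp_id = rec.id or f"{rec.chrom}:{rec.pos}"
                if rec.alts and len(rec.alts) > 1:
                    snp_id = f"{snp_id}_{alt}"
                if interval["strand"] == "+":
                    records.append(
                        SnpRecord(snp_id, left, right, rec.ref, alt, snp_class)
                    )
                else:
                    records.append(
                        SnpRecord(
                            snp_id,
                            reverse_complement(right),
                            reverse_complement(left),
                            reverse_complement(rec.ref),
                            reverse_complement(alt),
                            snp_class,
                        )
                    )
    return records


def read_snps(
    path: str | Path,
    dialect: Literal["tsv", "vcf"] = "tsv",
    fasta_path: str | Path | None = None,
    cds_bed_path: str | Path | None = None,
) -> list[SnpRecord]:
    if dialect == "tsv":
        return read_snps_tsv(path)
    if dialect == "vcf":
        if fasta_path is None or cds_bed_path is None:
            raise ValueError("vcf dialect needs fasta_path and cds_bed_path")
        return read_snps_vcf(path, fasta_path, cds_bed_path)
    raise ValueError(f"unknown SNP dialect {dialect!r}")


# ------------------------------------------------------------------ tracks


def read_track(
    path: str | Path, kind: Literal["scalar", "binary"], population: str | None = None
) -> AnnotationTrack:
    """Annotation TSV: columns snp_id, value (and optionally population)."""
    frame = pd.read_csv(
        path, sep="\t", dtype={"snp_id": str}, float_precision="round_trip"
    )
    if not {"snp_id", "value"} <= set(frame.columns):
        raise ParseError(f"{path}: need columns snp_id, value")
    if population is not None and "population" in frame.columns:
        frame = frame[frame["population"] == population]
    values = dict(zip(frame["snp_id"], frame["value"].astype(float)))
    if kind == "binary":
        values = {k: int(v) for k, v in values.items()}
    return AnnotationTrack(kind, values, population=population)


def write_track(track: AnnotationTrack, path: str | Path) -> None:
    frame = pd.DataFrame(
        sorted(track.values.items()), columns=["snp_id", "value"]
    )
    if track.population is not None:
        frame["population"] = track.population
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- matrices


def read_genotype_matrix(path: str | Path) -> GenotypeMatrix:
    frame = pd.read_csv(
        path, sep="\t", index_col=0, na_values=["NA"], float_precision="round_trip"
    )
    return GenotypeMatrix(frame.astype(float))


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    frame = pd.read_csv(
        path, sep="\t", index_col=0, float_precision="round_trip"
    )
    return ExpressionMatrix(frame.astype(float))


def write_matrix(matrix: GenotypeMatrix | ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", na_rep="NA")


def read_snp_gene_map(path: str | Path) -> dict[str, str]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if not {"snp_id", "gene_id"} <= set(frame.columns):
        raise ParseError(f"{path}: need columns snp_id, gene_id")
    return dict(zip(frame["snp_id"], frame["gene_id"]))


def write_snp_gene_map(mapping: Mapping[str, str], path: str | Path) -> None:
    frame = pd.DataFrame(sorted(mapping.items()), columns=["snp_id", "gene_id"])
    frame.to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------- results


def write_sites(sites: Mapping[str, Iterable[TargetSite]], path: str | Path) -> None:
    """Site report: window_id, mirna, site_type, start, end (0-based half-open)."""
    rows = [
        (window_id, s.mirna_name, s.site_type, s.start, s.end)
        for window_id, window_sites in sites.items()
        for s in window_sites
    ]
    frame = pd.DataFrame(rows, columns=["window_id", "mirna", "site_type", "start", "end"])
    frame.to_csv(path, sep="\t", index=False)


def write_changes(changes: Iterable[RegulationChange], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            (c.snp_id, int(c.changed), ",".join(sorted(c.gained)), ",".join(sorted(c.lost)))
            for c in changes
        ],
        columns=["snp_id", "changed", "gained", "lost"],
    )
    frame.to_csv(path, sep="\t", index=False)


def read_changes(path: str | Path) -> list[RegulationChange]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for row in frame.itertuples(index=False):
        gained = frozenset(row.gained.split(",")) - {""}
        lost = frozenset(row.lost.split(",")) - {""}
        out.append(RegulationChange(row.snp_id, gained, lost))
    return out


def enrichment_row(result: EnrichmentResult) -> dict:
    t = result.table
    return {
        "a": t.a,
        "b": t.b,
        "c": t.c,
        "d": t.d,
        "odds_ratio": result.odds_ratio,
        "p_value": result.p_value,
        "method": result.method,
        "alternative": result.alternative,
        "mode": result.mode or "",
        "population": result.population or "",
        "degenerate": int(result.degenerate),
    }


def write_enrichment_results(
    results: Iterable[EnrichmentResult], path: str | Path
) -> None:
    pd.DataFrame([enrichment_row(r) for r in results]).to_csv(path, sep="\t", index=False)


def write_permutation_result(
    result: PermutationResult, path: str | Path, histogram_path: str | Path | None = None
) -> None:
    frame = pd.DataFrame(
        [
            {
                "observed": result.observed,
                "expected": result.expected,
                "p_value": result.p_value,
                "n_perm": result.n_perm,
                "seed": result.seed,
                "alternative": result.alternative,
            }
        ]
    )
    frame.to_csv(path, sep="\t", index=False)
    if histogram_path is not None:
        hist = null_histogram(result)
        pd.DataFrame(hist, columns=["overlap", "frequency"]).to_csv(
            histogram_path, sep="\t", index=False
        )


def write_assoc_results(results: Iterable[AssocResult], path: str | Path) -> None:
    assoc_frame(results).to_csv(path, sep="\t", index=False)


def write_bundle(bundle, out_dir: str | Path) -> dict[str, str]:
    """Write a :class:`~mirsnp.simulate.SimulatedBundle` as a TSV input set.

    Returns the path map (keys: catalog, snps, truth, snp_gene_map,
    genotypes, expression, plus one per annotation track) suitable for
    building a :class:`~mirsnp.pipeline.PipelineConfig`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    paths["catalog"] = str(out / "catalog.tsv")
    write_mirna_catalog(bundle.catalog, paths["catalog"])
    paths["snps"] = str(out / "snps.tsv")
    write_snps_tsv(bundle.snps, paths["snps"])
    paths["truth"] = str(out / "truth.tsv")
    bundle.truth.astype(int).rename_axis("snp_id").to_csv(paths["truth"], sep="\t")
    for name, track in bundle.tracks.items():
        paths[name] = str(out / f"{name}.tsv")
        write_track(track, paths[name])
    paths["snp_gene_map"] = str(out / "snp_gene_map.tsv")
    write_snp_gene_map(bundle.snp_to_gene, paths["snp_gene_map"])
    paths["genotypes"] = str(out / "genotypes.tsv")
    write_matrix(bundle.genotypes, paths["genotypes"])
    paths["expression"] = str(out / "expression.tsv")
    write_matrix(bundle.expression, paths["expression"])
    return paths


def write_summary_json(summary: Mapping, path: str | Path) -> None:
    def _default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON-serialisable: {type(obj)}")

    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True, default=_default) + "\n")
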