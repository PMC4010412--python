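"""Readers and writers for the plain-text interchange formats.

GTF is 1-based inclusive on disk and 0-based half-open in memory; the
conversion is exact in both directions.  Cleavage sites travel as BED6
(0-based half-open, name = gene:rank, strand mandatory); alignments as a
headerless TSV (chrom, start, end, strand, sample_id, unique_flag); count
matrices as TSV with a header row of sample ids; ground truth as YAML.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Union

import pandas as pd
import yaml
from gffutils.feature import feature_from_line

from .apa import CleavageSite
from .catalog import ExonChain, TranscriptCatalog, TranscriptModel
from .errors import ParseError
from .quantify import ALIGNMENT_COLUMNS
from .synthetic import GroundTruth

PathLike = Union[str, Path]


# ----------------------------------------------------------------------- GTF


def write_gtf(catalog: TranscriptCatalog, path: PathLike) -> None:
    """Write one 'exon' feature line per exon, in catalog order."""
    with open(path, "w") as fh:
        for t in catalog:
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'rna_class "{t.rna_class}";'
            )
            for s, e in t.chain.exons:
                fh.write(
                    f"{t.chain.chrom}\tstrandtx\texon\t{s + 1}\t{e}\t.\t"
                    f"{t.chain.strand}\t.\t{attrs}\n"
                )


def read_gtf(path: PathLike) -> TranscriptCatalog:
    """Parse exon features into a catalog.

    gene_id and transcript_id attributes are mandatory; a '.' strand is
    rejected (the downstream counting rules are strand-specific).  An
    rna_class attribute is honored when present and defaults to 'coding'.
    """
    exons: Dict[str, List] = {}
    meta: Dict[str, Dict[str, str]] = {}
    order: List[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line, strict=False)
            except Exception as exc:
                raise ParseError(f"malformed GTF record: {exc}", lineno) from exc
            if feat.featuretype != "exon":
                continue
            if feat.strand not in ("+", "-"):
                raise ParseError(
                    f"unstranded feature (strand {feat.strand!r}); "
                    "a strand-specific analysis requires '+' or '-'",
                    lineno,
                )
            try:
                gene_id = feat.attributes["gene_id"][0]
                transcript_id = feat.attributes["transcript_id"][0]
            except KeyError as exc:
                raise ParseError(f"missing mandatory attribute {exc}", lineno) from exc
            rna_class = feat.attributes.get("rna_class", ["coding"])[0]
            if transcript_id not in exons:
                order.append(transcript_id)
                exons[transcript_id] = []
                meta[transcript_id] = {
                    "gene_id": gene_id,
                    "chrom": feat.seqid,
                    "strand": feat.strand,
                    "rna_class": rna_class,
                }
            exons[transcript_id].append((feat.start - 1, feat.end))

    catalog = TranscriptCatalog()
    for tid in order:
        m = meta[tid]
        catalog.add(
            TranscriptModel(
                tid,
                m["gene_id"],
                ExonChain(m["chrom"], m["strand"], tuple(sorted(exons[tid]))),
                m["rna_class"],
            )
        )
    return catalog


# ----------------------------------------------------------------------- BED


def write_cleavage_bed(sites: Sequence[CleavageSite], path: PathLike) -> None:
    """BED6: the cleavage point as a 1-base interval, name = gene:rank."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.position}\t{s.position + 1}\t"
                f"{s.gene_id}:{s.rank}\t0\t{s.strand}\n"
            )


def read_cleavage_bed(path: PathLike) -> List[CleavageSite]:
    sites = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ParseError("cleavage BED needs 6 columns (strand mandatory)", lineno)
            chrom, start, _end, name, _score, strand = fields[:6]
            if strand not in ("+", "-"):
                raise ParseError(f"invalid strand {strand!r}", lineno)
            try:
                gene_id, rank = name.rsplit(":", 1)
                sites.append(CleavageSite(gene_id, chrom, int(start), strand, int(rank)))
            except ValueError as exc:
                raise ParseError(f"bad site name {name!r} (expected gene:rank)", lineno) from exc
    return sites


# ------------------------------------------------------------ alignments TSV


def write_alignments(alignments: pd.DataFrame, path: PathLike) -> None:
    df = alignments.copy()
    df["unique"] = df["unique"].astype(int)
    df.to_csv(path, sep="\t", header=False, index=False)


def read_alignments(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=list(ALIGNMENT_COLUMNS),
        dtype={"chrom": str, "start": int, "end": int, "strand": str,
               "sample_id": str, "unique": int},
    )
    df["unique"] = df["unique"].astype(bool)
    return df


# ------------------------------------------------------------------ counts TSV


def write_counts(counts: pd.DataFrame, path: PathLike) -> None:
    counts.to_csv(path, sep="\t", index_label="id")


def read_counts(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="id")


# ------------------------------------------------------------------- YAML


def write_ground_truth(truth: GroundTruth, path: PathLike) -> None:
    payload = dataclasses.asdict(truth)
    payload["true_apa"] = {g: list(v) for g, v in payload["true_apa"].items()}
    payload["true_isoform_shifts"] = {
        g: list(v) for g, v in payload["true_isoform_shifts"].items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def read_ground_truth(path: PathLike) -> GroundTruth:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    payload["true_apa"] = {g: tuple(v) for g, v in payload["true_apa"].items()}
    payload["true_isoform_shifts"] = {
        g: tuple(v) for g, v in payload["true_isoform_shifts"].items()
    }
    return GroundTruth(**payload)
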