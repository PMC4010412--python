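"""Strand-aware read assignment and counting.

The counting rules, applied per read:

* a read overlapping exons of transcripts of exactly one gene on the matching
  strand is a *sense* read of those transcripts (counted once per transcript,
  once at gene level);
* a read overlapping only the opposite strand of exactly one coding gene's
  exons quantifies *antisense* transcription of that gene;
* reads touching two or more genes, or two or more RNA classes, are excluded
  (multi-gene / multi-class), as are reads overlapping nothing (intergenic)
  and antisense reads over non-coding features (antisense_noncoding).

Sense assignment takes precedence over antisense: a read compatible with a
sense transcript is never counted as antisense of an overlapping opposite-
strand coding gene.  "Overlap" means at least one base of exonic overlap.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd

from .catalog import TranscriptCatalog, TranscriptModel, REPEAT_SUBCLASSES, SMALL_RNA_SUBCLASSES

ALIGNMENT_COLUMNS = ("chrom", "start", "end", "strand", "sample_id", "unique")


@dataclass(frozen=True)
class AlignmentRecord:
    """One strand-tagged single-end read placement (0-based half-open)."""

    chrom: str
    start: int
    end: int
    strand: str
    sample_id: str
    unique: bool = True

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("alignment end must be > start")
        if self.strand not in ("+", "-"):
            raise ValueError("alignment strand must be '+' or '-'")


def alignments_to_frame(records: Iterable[AlignmentRecord]) -> pd.DataFrame:
    """Build the TSV-dialect alignment frame from records."""
    rows = [(r.chrom, r.start, r.end, r.strand, r.sample_id, r.unique) for r in records]
    return pd.DataFrame(rows, columns=list(ALIGNMENT_COLUMNS))


def _as_frame(alignments) -> pd.DataFrame:
    if isinstance(alignments, pd.DataFrame):
        return alignments
    return alignments_to_frame(alignments)


@dataclass(frozen=True)
class Assignment:
    """Outcome of assigning one read: kind in {'sense', 'antisense', 'excluded'}."""

    kind: str
    transcripts: Tuple[str, ...] = ()
    gene_id: Optional[str] = None
    reason: Optional[str] = None


@dataclass
class CountMatrix:
    """Read counts by transcript/gene x sample, split by orientation.

    ``sense``: transcript-level sense counts (a read compatible with several
    isoforms of one gene increments each of them).
    ``gene``: gene-level counts, each read counted once per gene.
    ``antisense``: per coding gene, reads on the opposite strand of its exons.
    ``unique``: transcript-level counts of uniquely-assignable unique-flagged
    reads (compatible with exactly one transcript), used by the
    high-confidence filter.
    ``excluded``: per-sample exclusion tallies by reason.
    """

    sense: pd.DataFrame
    gene: pd.DataFrame
    antisense: pd.DataFrame
    unique: pd.DataFrame
    excluded: pd.DataFrame

    @property
    def samples(self) -> List[str]:
        return list(self.sense.columns)


@dataclass(frozen=True)
class ClassSummary:
    """Per-class read totals, class length, and molar concentration.

    ``totals``: class x sample read totals (sense counts only).
    ``length``: total spliced length of each class, in bases.
    ``concentration``: pooled reads per base of class sequence, the molar-
    concentration adjustment used to compare classes of very different sizes.
    """

    totals: pd.DataFrame
    length: pd.Series
    concentration: pd.Series


def build_exon_lookup(catalog: TranscriptCatalog):
    """Interval index over exons: chrom -> IntervalTree of (transcript) data."""
    return catalog.exon_index()


def assign_read(
    read: AlignmentRecord,
    catalog: TranscriptCatalog,
    index=None,
) -> Assignment:
    """Assign one read according to the strand-aware counting rules."""
    index = index if index is not None else catalog.exon_index()
    tree = index.get(read.chrom)
    hits: List[TranscriptModel] = (
        [iv.data for iv in tree.overlap(read.start, read.end)] if tree is not None else []
    )
    if not hits:
        return Assignment("excluded", reason="intergenic")

    sense_hits = [t for t in hits if t.chain.strand == read.strand]
    if sense_hits:
        genes = {t.gene_id for t in sense_hits}
        classes = {catalog.gene_class(g) for g in genes}
        if len(classes) > 1:
            return Assignment("excluded", reason="multi_class")
        if len(genes) > 1:
            return Assignment("excluded", reason="multi_gene")
        gene = next(iter(genes))
        tids = tuple(sorted({t.transcript_id for t in sense_hits}))
        return Assignment("sense", transcripts=tids, gene_id=gene)

    # antisense: only over coding genes
    anti_genes = {t.gene_id for t in hits if catalog.gene_class(t.gene_id) == "coding"}
    if not anti_genes:
        return Assignment("excluded", reason="antisense_noncoding")
    if len(anti_genes) > 1:
        return Assignment("excluded", reason="multi_gene")
    return Assignment("antisense", gene_id=next(iter(anti_genes)))


EXCLUSION_REASONS = ("intergenic", "multi_gene", "multi_class", "antisense_noncoding")


def count(
    alignments,
    catalog: TranscriptCatalog,
    samples: Optional[Sequence[str]] = None,
) -> CountMatrix:
    """Count an alignment stream against a catalog.

    ``alignments`` is an alignment frame or an iterable of
    :class:`AlignmentRecord`.  Unknown chromosomes raise; full label sets are
    returned even when no read maps to them (zero rows/columns kept).

    Counting is order-invariant: the result depends only on the multiset of
    reads.
    """
    df = _as_frame(alignments)
    known_chroms = set(catalog.exon_index())
    if len(df):
        bad = set(df["chrom"].unique()) - known_chroms
        if bad:
            raise ValueError(f"alignments reference unknown chromosomes: {sorted(bad)}")

    if samples is None:
        samples = sorted(df["sample_id"].unique()) if len(df) else []
    samples = list(samples)
    tids = [t.transcript_id for t in catalog]
    gids = catalog.gene_ids
    coding_gids = [g for g in gids if catalog.gene_class(g) == "coding"]
    s_idx = {s: j for j, s in enumerate(samples)}
    t_idx = {t: i for i, t in enumerate(tids)}
    g_idx = {g: i for i, g in enumerate(gids)}
    cg_idx = {g: i for i, g in enumerate(coding_gids)}

    sense = np.zeros((len(tids), len(samples)), dtype=np.int64)
    gene = np.zeros((len(gids), len(samples)), dtype=np.int64)
    anti = np.zeros((len(coding_gids), len(samples)), dtype=np.int64)
    uniq = np.zeros((len(tids), len(samples)), dtype=np.int64)
    excl = np.zeros((len(EXCLUSION_REASONS), len(samples)), dtype=np.int64)
    r_idx = {r: i for i, r in enumerate(EXCLUSION_REASONS)}

    index = catalog.exon_index()
    for row in df.itertuples(index=False):
        rec = AlignmentRecord(row.chrom, int(row.start), int(row.end), row.strand,
                              row.sample_id, bool(row.unique))
        j = s_idx.get(rec.sample_id)
        if j is None:
            continue
        a = assign_read(rec, catalog, index)
        if a.kind == "sense":
            for tid in a.transcripts:
                sense[t_idx[tid], j] += 1
            gene[g_idx[a.gene_id], j] += 1
            if len(a.transcripts) == 1 and rec.unique:
                uniq[t_idx[a.transcripts[0]], j] += 1
        elif a.kind == "antisense":
            anti[cg_idx[a.gene_id], j] += 1
        else:
            excl[r_idx[a.reason], j] += 1

    return CountMatrix(
        sense=pd.DataFrame(sense, index=tids, columns=samples),
        gene=pd.DataFrame(gene, index=gids, columns=samples),
        antisense=pd.DataFrame(anti, index=coding_gids, columns=samples),
        unique=pd.DataFrame(uniq, index=tids, columns=samples),
        excluded=pd.DataFrame(excl, index=list(EXCLUSION_REASONS), columns=samples),
    )


def summarize_classes(
    counts: CountMatrix,
    catalog: TranscriptCatalog,
    exclude_classes: Sequence[str] = (),
) -> ClassSummary:
    """Aggregate sense counts to major classes and repeat/small-RNA subclasses.

    The summary contains one row per major class plus one per present subclass
    (named 'repeat:ERV1' etc.).  ``length`` is the summed spliced length of all
    member transcripts; ``concentration`` is pooled reads / class length.
    rRNA-style exclusions are supported through ``exclude_classes``.
    """
    labels_major: Dict[str, str] = {}
    labels_full: Dict[str, str] = {}
    for t in catalog:
        if t.major_class in exclude_classes or t.rna_class in exclude_classes:
            continue
        labels_major[t.transcript_id] = t.major_class
        if t.subclass is not None:
            labels_full[t.transcript_id] = t.rna_class

    sense = counts.sense
    rows = {}
    lengths = {}
    for label_map in (labels_major, labels_full):
        groups: Dict[str, List[str]] = {}
        for tid, lab in label_map.items():
            groups.setdefault(lab, []).append(tid)
        for lab, tids in groups.items():
            present = [t for t in tids if t in sense.index]
            rows[lab] = sense.loc[present].sum(axis=0)
            lengths[lab] = sum(catalog.get(t).chain.length for t in tids)

    totals = pd.DataFrame(rows).T
    length = pd.Series(lengths, dtype=float)
    pooled = totals.sum(axis=1).astype(float)
    concentration = pooled / length
    return ClassSummary(totals=totals, length=length, concentration=concentration)
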