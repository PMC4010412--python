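"""Transcript data model, Cuffcompare-style class codes, and novelty/confidence filters.

The unit of annotation is a :class:`TranscriptModel`: an exon chain on a strand,
belonging to a gene, carrying exactly one RNA class.  All internal coordinates
are 0-based half-open genomic intervals; GTF conversion happens in :mod:`strandtx.io`.

Class codes relate an assembled (query) transcript to a reference annotation:

``=``
    identical ordered exon-exon junction chain as some same-strand reference
    transcript (single-exon queries additionally require exonic overlap, since
    their junction chain is empty);
``j``
    shares at least one junction with a same-strand reference transcript but is
    not ``=``;
``o``
    overlaps a reference transcript (either strand) without sharing a junction;
    purely intronic overlaps are folded into this code to keep the four-code
    set a partition;
``u``
    overlaps no reference transcript at all (exon or intron, either strand).

On top of the codes sit two filters for novel transcription: *high novelty*
(absence from a set of auxiliary annotation tracks) and *high confidence*
(unique-read support breadth and, for loci, sequencing depth).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from intervaltree import IntervalTree

from .errors import ConfigurationError

MAJOR_CLASSES = ("coding", "lncRNA", "smallRNA", "repeat", "novel_locus", "novel_isoform")
SMALL_RNA_SUBCLASSES = ("priMiRNA", "snoRNA_CD", "snoRNA_HACA", "scaRNA")
REPEAT_SUBCLASSES = ("ERV1", "ERVK", "ERVL", "LTR_other", "L1", "SINE_Alu", "SINE1_7SL")

_VALID_CLASSES = (
    {"coding", "lncRNA", "novel_locus", "novel_isoform"}
    | {f"smallRNA:{s}" for s in SMALL_RNA_SUBCLASSES}
    | {f"repeat:{s}" for s in REPEAT_SUBCLASSES}
)

Junction = Tuple[int, int]  # (donor exon end, acceptor exon start), 0-based half-open


def validate_rna_class(rna_class: str) -> str:
    if rna_class not in _VALID_CLASSES:
        raise ConfigurationError(
            f"unknown RNA class {rna_class!r}; expected one of {sorted(_VALID_CLASSES)}"
        )
    return rna_class


@dataclass(frozen=True)
class ExonChain:
    """An ordered, non-overlapping exon chain on one strand.

    ``exons`` are (start, end) pairs in 0-based half-open genomic coordinates,
    sorted by start regardless of strand.
    """

    chrom: str
    strand: str
    exons: Tuple[Tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        if not exons:
            raise ValueError("exon chain must contain at least one exon")
        prev_end = None
        for s, e in exons:
            if e <= s:
                raise ValueError(f"exon ({s}, {e}) has end <= start")
            if prev_end is not None and s < prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = e
        object.__setattr__(self, "exons", exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def length(self) -> int:
        """Spliced (exonic) length in bases."""
        return sum(e - s for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def junctions(self) -> Tuple[Junction, ...]:
        """Ordered exon-exon junctions as (donor end, acceptor start) pairs."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )

    def overlaps_exonic(self, other: "ExonChain") -> bool:
        if self.chrom != other.chrom:
            return False
        for s1, e1 in self.exons:
            for s2, e2 in other.exons:
                if s1 < e2 and s2 < e1:
                    return True
        return False

    def overlaps_span(self, other: "ExonChain") -> bool:
        return (
            self.chrom == other.chrom and self.start < other.end and other.start < self.end
        )


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript: exon chain + gene membership + one RNA class."""

    transcript_id: str
    gene_id: str
    chain: ExonChain
    rna_class: str

    def __post_init__(self):
        validate_rna_class(self.rna_class)

    @property
    def major_class(self) -> str:
        return self.rna_class.split(":", 1)[0]

    @property
    def subclass(self) -> Optional[str]:
        parts = self.rna_class.split(":", 1)
        return parts[1] if len(parts) == 2 else None


class TranscriptCatalog:
    """An ordered collection of transcripts with interval indexes.

    Iteration order is insertion order, which keeps serialized output
    deterministic for a deterministic construction order.
    """

    def __init__(self, transcripts: Iterable[TranscriptModel] = ()):
        self._transcripts: Dict[str, TranscriptModel] = {}
        self._genes: Dict[str, List[str]] = {}
        self._exon_index: Optional[Dict[str, IntervalTree]] = None
        self._span_index: Optional[Dict[str, IntervalTree]] = None
        for t in transcripts:
            self.add(t)

    def add(self, t: TranscriptModel) -> None:
        if t.transcript_id in self._transcripts:
            raise ValueError(f"duplicate transcript id {t.transcript_id!r}")
        self._transcripts[t.transcript_id] = t
        self._genes.setdefault(t.gene_id, []).append(t.transcript_id)
        self._exon_index = None
        self._span_index = None

    def __len__(self) -> int:
        return len(self._transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self._transcripts.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._transcripts

    def get(self, transcript_id: str) -> TranscriptModel:
        return self._transcripts[transcript_id]

    @property
    def gene_ids(self) -> List[str]:
        return list(self._genes)

    def transcripts_of_gene(self, gene_id: str) -> List[TranscriptModel]:
        return [self._transcripts[t] for t in self._genes[gene_id]]

    def gene_class(self, gene_id: str) -> str:
        """Major class of a gene: the class of its non-novel-isoform transcripts.

        A gene hosting both annotated coding isoforms and a novel isoform is a
        coding gene; novel-isoform membership does not create a class conflict.
        """
        classes = {t.major_class for t in self.transcripts_of_gene(gene_id)}
        non_novel = classes - {"novel_isoform"}
        if non_novel:
            if len(non_novel) > 1:  # should not happen for well-formed catalogs
                raise ValueError(f"gene {gene_id!r} has conflicting classes {non_novel}")
            return next(iter(non_novel))
        return "novel_isoform"

    def by_class(self, rna_class: str) -> List[TranscriptModel]:
        """Transcripts of a full class ('repeat:ERV1') or a major class ('repeat')."""
        if ":" in rna_class or rna_class in ("coding", "lncRNA", "novel_locus", "novel_isoform"):
            return [t for t in self if t.rna_class == rna_class]
        return [t for t in self if t.major_class == rna_class]

    def subset(self, predicate: Callable[[TranscriptModel], bool]) -> "TranscriptCatalog":
        return TranscriptCatalog(t for t in self if predicate(t))

    # ------------------------------------------------------------------ indexes

    def exon_index(self) -> Dict[str, IntervalTree]:
        """chrom -> IntervalTree of exons; interval data is the transcript."""
        if self._exon_index is None:
            idx: Dict[str, IntervalTree] = {}
            for t in self:
                tree = idx.setdefault(t.chain.chrom, IntervalTree())
                for s, e in t.chain.exons:
                    tree.addi(s, e, t)
            self._exon_index = idx
        return self._exon_index

    def span_index(self) -> Dict[str, IntervalTree]:
        """chrom -> IntervalTree of full transcript spans (exons + introns)."""
        if self._span_index is None:
            idx: Dict[str, IntervalTree] = {}
            for t in self:
                idx.setdefault(t.chain.chrom, IntervalTree()).addi(
                    t.chain.start, t.chain.end, t
                )
            self._span_index = idx
        return self._span_index

    def _span_hits(self, chain: ExonChain) -> List[TranscriptModel]:
        tree = self.span_index().get(chain.chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(chain.start, chain.end)]


@dataclass(frozen=True)
class AnnotationTrackSet:
    """Named auxiliary annotation tracks used by the high-novelty filter."""

    tracks: Tuple[Tuple[str, TranscriptCatalog], ...]

    def __post_init__(self):
        names = [n for n, _ in self.tracks]
        if len(set(names)) != len(names):
            raise ValueError("track names must be unique")

    @classmethod
    def from_dict(cls, tracks: Mapping[str, TranscriptCatalog]) -> "AnnotationTrackSet":
        return cls(tuple(tracks.items()))

    def __iter__(self) -> Iterator[Tuple[str, TranscriptCatalog]]:
        return iter(self.tracks)


@dataclass(frozen=True)
class ConfidenceThresholds:
    """Read-support thresholds for calling a novel transcript high-confidence."""

    min_unique_reads: int = 10
    min_samples: int = 6
    min_depth: float = 10.0

    def __post_init__(self):
        if self.min_unique_reads <= 0 or self.min_samples <= 0 or self.min_depth <= 0:
            raise ValueError("confidence thresholds must be positive")


# ---------------------------------------------------------------------- class codes


def classify_transcript(query: TranscriptModel, reference: TranscriptCatalog) -> str:
    """Assign one of the class codes {"=", "j", "o", "u"} to *query*.

    See the module docstring for the code definitions.  Exactly one code is
    returned for any query (the codes partition the outcome space).
    """
    chain = query.chain
    hits = reference._span_hits(chain)
    qj = chain.junctions
    same_strand = [t for t in hits if t.chain.strand == chain.strand]

    for t in same_strand:
        if t.chain.junctions == qj:
            if qj or chain.overlaps_exonic(t.chain):
                return "="
    if qj:
        qj_set = set(qj)
        for t in same_strand:
            if qj_set & set(t.chain.junctions):
                return "j"
    if hits:
        return "o"
    return "u"


def is_high_novelty(
    query: TranscriptModel, tracks: AnnotationTrackSet, kind: str
) -> bool:
    """Apply the high-novelty filter against auxiliary annotation tracks.

    kind='locus' (class "u" queries): high novelty iff the query span overlaps
    no transcript span — exons or introns, either strand — in any track.

    kind='isoform' (class "j" queries): high novelty iff no track transcript
    contains the query's full junction chain AND at least one query junction is
    absent from every track.
    """
    chain = query.chain
    if kind == "locus":
        for _, track in tracks:
            if track._span_hits(chain):
                return False
        return True
    if kind == "isoform":
        qj = set(chain.junctions)
        if not qj:
            return False
        known_junctions: set = set()
        full_chain_known = False
        for _, track in tracks:
            for t in track:
                if t.chain.chrom != chain.chrom or t.chain.strand != chain.strand:
                    continue
                tj = set(t.chain.junctions)
                known_junctions |= tj
                if qj <= tj:
                    full_chain_known = True
        has_unknown = bool(qj - known_junctions)
        return has_unknown and not full_chain_known
    raise ValueError(f"kind must be 'locus' or 'isoform', got {kind!r}")


def is_high_confidence(
    query: TranscriptModel,
    unique_counts: "pd.DataFrame",
    thresholds: ConfidenceThresholds = ConfidenceThresholds(),
    kind: str = "locus",
    read_length: int = 50,
) -> bool:
    """Apply the high-confidence read-support filter.

    ``unique_counts`` is a transcripts x samples table of uniquely mapped read
    counts (reads compatible with no other gene and no other isoform of the
    same gene).  Both kinds require >= ``min_unique_reads`` in at least
    ``min_samples`` samples; loci additionally require pooled depth
    (unique reads x read length / spliced locus length) strictly above
    ``min_depth``.
    """
    if kind not in ("locus", "isoform"):
        raise ValueError(f"kind must be 'locus' or 'isoform', got {kind!r}")
    if query.transcript_id not in unique_counts.index:
        raise KeyError(f"unknown transcript id {query.transcript_id!r} in unique counts")
    row = unique_counts.loc[query.transcript_id]
    breadth_ok = int((row >= thresholds.min_unique_reads).sum()) >= thresholds.min_samples
    if kind == "isoform":
        return breadth_ok
    depth = float(row.sum()) * read_length / query.chain.length
    return breadth_ok and depth > thresholds.min_depth


def classification_report(
    queries: Iterable[TranscriptModel],
    reference: TranscriptCatalog,
    tracks: AnnotationTrackSet,
    unique_counts: "pd.DataFrame",
    thresholds: ConfidenceThresholds = ConfidenceThresholds(),
    read_length: int = 50,
) -> "pd.DataFrame":
    """Classify each query and evaluate both filters; one row per query.

    Novelty and confidence are evaluated with kind='locus' for "u" queries and
    kind='isoform' for "j" queries; other codes get high_novelty=False.
    """
    rows = []
    for q in queries:
        code = classify_transcript(q, reference)
        kind = {"u": "locus", "j": "isoform"}.get(code)
        novelty = is_high_novelty(q, tracks, kind) if kind else False
        confidence = (
            is_high_confidence(q, unique_counts, thresholds, kind, read_length)
            if kind and q.transcript_id in unique_counts.index
            else False
        )
        rows.append(
            {
                "transcript_id": q.transcript_id,
                "gene_id": q.gene_id,
                "rna_class": q.rna_class,
                "code": code,
                "high_novelty": novelty,
                "high_confidence": confidence,
            }
        )
    return pd.DataFrame(rows)
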