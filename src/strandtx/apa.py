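"""Alternative-polyadenylation (APA) analysis from strand-specific read starts.

Every annotated cleavage site gets an isoform-expression estimate: the number
of reads whose 5' end falls in the 200-base window transcriptionally upstream
of the cleavage point.  Per gene, the most proximal and most distal supported
sites form a 2x2 table (proximal/distal x control/case); the relative ratio

    R = (proximal_case / distal_case) / (proximal_control / distal_control)

together with a two-sided Fisher exact p-value yields a longer/shorter 3'UTR
call.  R > cutoff means the case group shifted toward proximal usage, i.e. a
*shorter* 3'UTR; 1/R > cutoff means *longer*.

The Fisher test here is implemented with exact integer arithmetic
(hypergeometric point-probability method): outcome probabilities with a common
denominator are compared as integers, so tie handling is exact rather than
float-tolerance based.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CleavageSite:
    """An annotated mRNA cleavage point.

    ``position`` is a 0-based boundary coordinate: on '+' the transcript's last
    base is position-1 and the upstream window is [position-200, position); on
    '-' the transcript's last base is position and the window is
    [position, position+200).  ``rank`` orders sites along the transcript's 3'
    direction: rank 1 is the most proximal (shortest 3'UTR).
    """

    gene_id: str
    chrom: str
    position: int
    strand: str
    rank: int

    def window(self, size: int = 200) -> Tuple[int, int]:
        if self.strand == "+":
            return (self.position - size, self.position)
        return (self.position, self.position + size)


@dataclass(frozen=True)
class ApaThresholds:
    window: int = 200
    min_isoform_reads: int = 10
    ratio_cutoff: float = 2.0
    p_cutoff: float = 0.01

    def __post_init__(self):
        if min(self.window, self.min_isoform_reads) <= 0 or min(
            self.ratio_cutoff, self.p_cutoff
        ) <= 0:
            raise ValueError("APA thresholds must be positive")


@dataclass(frozen=True)
class ApaGeneResult:
    gene_id: str
    proximal_control: int
    proximal_case: int
    distal_control: int
    distal_case: int
    relative_ratio: float
    oriented_ratio: float
    p: float
    call: str  # longer | shorter | unchanged

    def as_row(self) -> Dict[str, object]:
        return {
            "gene_id": self.gene_id,
            "proximal_control": self.proximal_control,
            "proximal_case": self.proximal_case,
            "distal_control": self.distal_control,
            "distal_case": self.distal_case,
            "relative_ratio": self.relative_ratio,
            "oriented_ratio": self.oriented_ratio,
            "p": self.p,
            "call": self.call,
        }


# ------------------------------------------------------------------ exact test


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 contingency table.

    Sums hypergeometric probabilities of all outcomes no more probable than the
    observed table, conditioning on both margins (point-probability method).
    A zero margin makes the table degenerate and returns p = 1.  Probabilities
    are compared as exact integers (common-denominator numerators), so equal
    probabilities are true ties.
    """
    (a, b), (c, d) = table
    a, b, c, d = int(a), int(b), int(c), int(d)
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be nonnegative integers")
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = r1 + r2
    if 0 in (r1, r2, c1, c2):
        return 1.0
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    if n > 2000:
        # large tables: log-space hypergeometric with a near-tie tolerance
        # (big-integer arithmetic would be exact but grows impractically)
        from scipy.special import gammaln

        k = np.arange(lo, hi + 1)
        logw = (
            gammaln(r1 + 1) - gammaln(k + 1) - gammaln(r1 - k + 1)
            + gammaln(r2 + 1) - gammaln(c1 - k + 1) - gammaln(r2 - c1 + k + 1)
        )
        logw -= logw.max()
        w = np.exp(logw)
        obs = w[a - lo]
        return float(min(1.0, w[w <= obs * (1.0 + 1e-7)].sum() / w.sum()))
    # numerator of P(k) with common denominator C(n, c1)
    weights = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)]
    obs = weights[a - lo]
    total = math.comb(n, c1)
    tail = sum(w for w in weights if w <= obs)
    return min(1.0, tail / total)


# ------------------------------------------------------------------ windows


def _read_five_prime(start: np.ndarray, end: np.ndarray, strand: np.ndarray) -> np.ndarray:
    """5'-most base of each read in transcript orientation (0-based)."""
    return np.where(strand == "+", start, end - 1)


def window_count(
    site: CleavageSite,
    alignments: "pd.DataFrame",
    samples: Optional[Iterable[str]] = None,
    window: int = 200,
) -> int:
    """Count reads whose 5' end lies in the upstream window of *site*.

    ``alignments`` is the TSV-dialect frame (chrom, start, end, strand,
    sample_id, unique).  Only reads on the site's strand and chromosome count;
    the window is half-open on both strands (see :class:`CleavageSite`).
    """
    lo, hi = site.window(window)
    df = alignments
    mask = (df["chrom"].values == site.chrom) & (df["strand"].values == site.strand)
    if samples is not None:
        mask &= np.isin(df["sample_id"].values, list(samples))
    pos = _read_five_prime(df["start"].values, df["end"].values, df["strand"].values)
    return int(np.count_nonzero(mask & (pos >= lo) & (pos < hi)))


def window_count_table(
    sites: Sequence[CleavageSite],
    alignments: "pd.DataFrame",
    groups: Mapping[str, str],
    window: int = 200,
) -> "pd.DataFrame":
    """Group-summed window counts for many sites at once.

    Returns a frame indexed by (gene_id, rank) with columns 'control', 'case',
    plus the site position and strand.  Group labels come from ``groups``
    (sample_id -> 'control' | 'case').
    """
    df = alignments
    start = df["start"].values
    end = df["end"].values
    strand = np.asarray(df["strand"].values, dtype=object)
    chrom = np.asarray(df["chrom"].values, dtype=object)
    pos = _read_five_prime(start, end, strand)
    is_case = np.array([groups[s] == "case" for s in df["sample_id"].values])

    # sorted 5' positions per (chrom, strand, group) for O(log n) window counts
    sorted_pos: Dict[Tuple[str, str, bool], np.ndarray] = {}
    for ch in pd.unique(chrom):
        for st in ("+", "-"):
            base = (chrom == ch) & (strand == st)
            for case_flag in (False, True):
                m = base & (is_case == case_flag)
                sorted_pos[(ch, st, case_flag)] = np.sort(pos[m])

    def _count(ch: str, st: str, case_flag: bool, lo: int, hi: int) -> int:
        arr = sorted_pos.get((ch, st, case_flag))
        if arr is None:
            return 0
        return int(np.searchsorted(arr, hi, "left") - np.searchsorted(arr, lo, "left"))

    rows = []
    for site in sites:
        lo, hi = site.window(window)
        rows.append(
            {
                "gene_id": site.gene_id,
                "rank": site.rank,
                "position": site.position,
                "strand": site.strand,
                "control": _count(site.chrom, site.strand, False, lo, hi),
                "case": _count(site.chrom, site.strand, True, lo, hi),
            }
        )
    return pd.DataFrame(rows).set_index(["gene_id", "rank"])


# ------------------------------------------------------------------ gene test


def gene_apa_test(
    gene_id: str,
    site_counts: Mapping[int, Tuple[int, int]],
    thresholds: ApaThresholds = ApaThresholds(),
) -> Optional[ApaGeneResult]:
    """Proximal-vs-distal usage test for one gene.

    ``site_counts`` maps site rank -> (control, case) group-summed window
    counts.  Sites with fewer than ``min_isoform_reads`` pooled reads are
    dropped; the most proximal and most distal surviving sites form the 2x2
    table.  Returns None (gene unanalyzable) when fewer than two sites survive.

    The ratio uses +0.5 on zero cells only; the exact test always sees the raw
    integer table.
    """
    supported = {
        r: (int(ctrl), int(case))
        for r, (ctrl, case) in site_counts.items()
        if ctrl + case >= thresholds.min_isoform_reads
    }
    if len(supported) < 2:
        return None
    prox_rank = min(supported)
    dist_rank = max(supported)
    p_ctrl, p_case = supported[prox_rank]
    d_ctrl, d_case = supported[dist_rank]

    def _h(x: int) -> float:
        return x if x > 0 else 0.5

    oriented = (_h(p_case) / _h(d_case)) / (_h(p_ctrl) / _h(d_ctrl))
    relative = max(oriented, 1.0 / oriented)
    p = fisher_exact_2x2([[p_ctrl, d_ctrl], [p_case, d_case]])
    call = "unchanged"
    if p < thresholds.p_cutoff:
        if oriented > thresholds.ratio_cutoff:
            call = "shorter"
        elif 1.0 / oriented > thresholds.ratio_cutoff:
            call = "longer"
    return ApaGeneResult(
        gene_id=gene_id,
        proximal_control=p_ctrl,
        proximal_case=p_case,
        distal_control=d_ctrl,
        distal_case=d_case,
        relative_ratio=relative,
        oriented_ratio=oriented,
        p=p,
        call=call,
    )


def apa_analysis(
    sites: Sequence[CleavageSite],
    alignments: "pd.DataFrame",
    groups: Mapping[str, str],
    thresholds: ApaThresholds = ApaThresholds(),
) -> Tuple["pd.DataFrame", int]:
    """Run the full APA analysis; returns (results frame, n unanalyzable genes)."""
    counts = window_count_table(sites, alignments, groups, thresholds.window)
    results: List[ApaGeneResult] = []
    skipped = 0
    for gene_id, sub in counts.groupby(level="gene_id", sort=False):
        site_counts = {
            int(rank): (int(row["control"]), int(row["case"]))
            for (_, rank), row in sub.iterrows()
        }
        res = gene_apa_test(str(gene_id), site_counts, thresholds)
        if res is None:
            skipped += 1
        else:
            results.append(res)
    frame = pd.DataFrame([r.as_row() for r in results])
    return frame, skipped
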