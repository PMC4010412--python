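"""Isoform relative-abundance shifts between groups.

Per gene, transcript counts are pooled within each group and converted to
isoform proportions; the per-isoform shift is tested with a two-sided Fisher
exact test on the 2x2 table [this isoform, all other isoforms] x [control,
case] — the change of relative abundance only, blind to gene-level
differential expression.  A gene is flagged when some isoform moves by at
least ``min_abs_delta`` (absolute proportion points) with p below
``p_cutoff``; both conditions are required.

Flagged isoforms feed a structural comparison: do case-favored isoforms carry
more exons than control-favored ones (Mann-Whitney two-sided)?
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .apa import fisher_exact_2x2
from .catalog import TranscriptCatalog


@dataclass(frozen=True)
class ShiftThresholds:
    min_abs_delta: float = 0.05
    p_cutoff: float = 0.05

    def __post_init__(self):
        if self.min_abs_delta <= 0 or self.p_cutoff <= 0:
            raise ValueError("shift thresholds must be positive")


@dataclass(frozen=True)
class ExonComplexityResult:
    mean_diff: float  # mean exon count, case-favored minus control-favored
    p: float
    n_case_favored: int
    n_control_favored: int
    underpowered: bool


def shift_test(
    iso_control: int, iso_case: int, rest_control: int, rest_case: int
) -> float:
    """Two-sided Fisher exact p for one isoform against the rest of its gene."""
    return fisher_exact_2x2([[iso_control, rest_control], [iso_case, rest_case]])


def isoform_proportions(
    transcript_counts: pd.DataFrame,
    catalog: TranscriptCatalog,
    groups: Mapping[str, str],
    thresholds: ShiftThresholds = ShiftThresholds(),
) -> Tuple[pd.DataFrame, int]:
    """Isoform proportions, deltas and shift tests for all multi-isoform genes.

    Counts are pooled (summed) within each group and rounded to integers for
    the exact test.  Single-isoform genes are excluded by construction; genes
    with a zero pooled total in either group are skipped and tallied.
    Returns (frame, n_skipped); the frame has one row per isoform with
    proportions, delta = case - control, p, and a ``flagged`` column applying
    both threshold conditions.
    """
    ctrl_cols = [s for s in transcript_counts.columns if groups[s] == "control"]
    case_cols = [s for s in transcript_counts.columns if groups[s] == "case"]
    rows = []
    skipped = 0
    for gene_id in catalog.gene_ids:
        tids = [
            t.transcript_id
            for t in catalog.transcripts_of_gene(gene_id)
            if t.transcript_id in transcript_counts.index
        ]
        if len(tids) < 2:
            continue
        sub = transcript_counts.loc[tids]
        pooled_ctrl = sub[ctrl_cols].sum(axis=1).round().astype(int)
        pooled_case = sub[case_cols].sum(axis=1).round().astype(int)
        tot_ctrl = int(pooled_ctrl.sum())
        tot_case = int(pooled_case.sum())
        if tot_ctrl == 0 or tot_case == 0:
            skipped += 1
            continue
        prop_ctrl = pooled_ctrl / tot_ctrl
        prop_case = pooled_case / tot_case
        for tid in tids:
            ic, ik = int(pooled_ctrl[tid]), int(pooled_case[tid])
            p = shift_test(ic, ik, tot_ctrl - ic, tot_case - ik)
            delta = float(prop_case[tid] - prop_ctrl[tid])
            rows.append(
                {
                    "gene_id": gene_id,
                    "isoform_id": tid,
                    "proportion_control": float(prop_ctrl[tid]),
                    "proportion_case": float(prop_case[tid]),
                    "delta": delta,
                    "pooled_control": ic,
                    "pooled_case": ik,
                    "p": p,
                    "flagged": abs(delta) >= thresholds.min_abs_delta
                    and p < thresholds.p_cutoff,
                }
            )
    frame = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "isoform_id",
            "proportion_control",
            "proportion_case",
            "delta",
            "pooled_control",
            "pooled_case",
            "p",
            "flagged",
        ],
    )
    return frame, skipped


def exon_complexity_compare(
    proportions: pd.DataFrame,
    catalog: TranscriptCatalog,
    min_per_direction: int = 5,
) -> ExonComplexityResult:
    """Compare exon counts of case-favored vs control-favored flagged isoforms.

    Case-favored: flagged isoforms with delta > 0; control-favored: delta < 0.
    Underpowered (fewer than ``min_per_direction`` isoforms in either
    direction) results carry NaN statistics.
    """
    flagged = proportions[proportions["flagged"]]
    case_ids = flagged.loc[flagged["delta"] > 0, "isoform_id"]
    ctrl_ids = flagged.loc[flagged["delta"] < 0, "isoform_id"]
    case_exons = np.array([catalog.get(t).chain.n_exons for t in case_ids])
    ctrl_exons = np.array([catalog.get(t).chain.n_exons for t in ctrl_ids])
    underpowered = len(case_exons) < min_per_direction or len(ctrl_exons) < min_per_direction
    if len(case_exons) == 0 or len(ctrl_exons) == 0:
        return ExonComplexityResult(np.nan, np.nan, len(case_exons), len(ctrl_exons), True)
    mean_diff = float(case_exons.mean() - ctrl_exons.mean())
    if np.ptp(np.concatenate([case_exons, ctrl_exons])) == 0:
        p = 1.0
    else:
        p = float(
            stats.mannwhitneyu(case_exons, ctrl_exons, alternative="two-sided").pvalue
        )
    return ExonComplexityResult(mean_diff, p, len(case_exons), len(ctrl_exons), underpowered)
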