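"""Two-group correlation combining and its applications.

A gene-gene (or gene-feature) correlation is computed within the control and
case groups separately, each Pearson r is variance-stabilized with Fisher's
transformation z = atanh(r), the two z scores are averaged (unweighted by
default), and the average is mapped back with tanh to a single combined r.

Applications:

* sense-antisense coupling of coding genes,
* lncRNA / neighboring-coding-gene co-expression binned by distance, relative
  position and strand relation, against a random-pair baseline,
* depression of miRNA target sets relative to the non-target background.

Correlations are computed on log2(x+1)-transformed normalized counts.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import TranscriptCatalog, TranscriptModel

_CLIP = 1.0 - 1e-12


@dataclass(frozen=True)
class CorrelationRecord:
    pair: Tuple[str, str]
    r_control: float
    r_case: float
    n_control: int
    n_case: int
    z_mean: float
    r_combined: float
    valid: bool = True


@dataclass(frozen=True)
class NeighborBinSpec:
    """Distance binning for lncRNA-coding neighbor analysis.

    ``bin_edges`` partition [0, max_distance]; pairs are additionally split by
    relative position (upstream/downstream of the coding gene, in the coding
    gene's orientation) and strand relation (same/opposite).
    """

    max_distance: int = 100_000
    bin_edges: Tuple[int, ...] = (0, 10_000, 25_000, 50_000, 100_000)
    n_random_pairs: int = 1000

    def __post_init__(self):
        if self.bin_edges[0] != 0 or self.bin_edges[-1] != self.max_distance:
            raise ValueError("bin edges must partition [0, max_distance]")
        if list(self.bin_edges) != sorted(set(self.bin_edges)):
            raise ValueError("bin edges must be strictly increasing")


def fisher_z(r: float) -> float:
    return float(np.arctanh(np.clip(r, -_CLIP, _CLIP)))


def combine_correlation(
    x: Sequence[float],
    y: Sequence[float],
    groups: Sequence[str],
    pair: Tuple[str, str] = ("x", "y"),
) -> CorrelationRecord:
    """Combine within-group Pearson correlations through Fisher's z.

    ``groups`` labels each observation 'control' or 'case'; each group needs
    at least 3 observations.  A zero-variance group makes the pair invalid
    (flagged, to be excluded from averages) rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    rs: Dict[str, float] = {}
    ns: Dict[str, int] = {}
    valid = True
    for g in ("control", "case"):
        mask = groups == g
        ns[g] = int(mask.sum())
        if ns[g] < 3:
            raise ValueError(f"group {g!r} needs >= 3 samples, got {ns[g]}")
        xg, yg = x[mask], y[mask]
        if np.ptp(xg) == 0 or np.ptp(yg) == 0:
            valid = False
            rs[g] = np.nan
        else:
            rs[g] = float(np.corrcoef(xg, yg)[0, 1])
    if not valid:
        return CorrelationRecord(pair, rs["control"], rs["case"], ns["control"],
                                 ns["case"], np.nan, np.nan, valid=False)
    z = 0.5 * (fisher_z(rs["control"]) + fisher_z(rs["case"]))
    return CorrelationRecord(
        pair, rs["control"], rs["case"], ns["control"], ns["case"], z, float(np.tanh(z))
    )


def _log_expr(counts: pd.DataFrame) -> pd.DataFrame:
    return np.log2(counts + 1.0)


# --------------------------------------------------------- sense / antisense


def sense_antisense_profile(
    sense: pd.DataFrame,
    antisense: pd.DataFrame,
    groups: Mapping[str, str],
) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Per-gene combined sense-antisense correlation and abundance ratios.

    Both matrices are gene x sample normalized counts; genes absent from
    either matrix are skipped and tallied.  Returns (per-gene frame, summary)
    where the summary holds the mean combined r over valid genes, the overall
    antisense:sense pooled read ratio, and skip/invalid tallies.
    """
    common = [g for g in sense.index if g in antisense.index]
    skipped = (len(sense.index) - len(common)) + (len(antisense.index) - len(common))
    cols = list(sense.columns)
    labels = [groups[s] for s in cols]
    ls = _log_expr(sense.loc[common, cols])
    la = _log_expr(antisense.loc[common, cols])

    rows = []
    for g in common:
        rec = combine_correlation(ls.loc[g].values, la.loc[g].values, labels, (g, g))
        s_total = float(sense.loc[g, cols].sum())
        a_total = float(antisense.loc[g, cols].sum())
        rows.append(
            {
                "gene_id": g,
                "r_control": rec.r_control,
                "r_case": rec.r_case,
                "r_combined": rec.r_combined,
                "valid": rec.valid,
                "sense_total": s_total,
                "antisense_total": a_total,
                "antisense_sense_ratio": a_total / s_total if s_total > 0 else np.nan,
            }
        )
    columns = ["gene_id", "r_control", "r_case", "r_combined", "valid",
               "sense_total", "antisense_total", "antisense_sense_ratio"]
    frame = pd.DataFrame(rows, columns=columns).set_index("gene_id")
    valid = frame[frame["valid"].astype(bool)] if len(frame) else frame
    summary = {
        "mean_r_combined": float(valid["r_combined"].mean()) if len(valid) else np.nan,
        "n_pairs": int(len(valid)),
        "n_skipped": int(skipped),
        "n_invalid": int((~frame["valid"]).sum()),
        "antisense_sense_pooled_ratio": float(
            frame["antisense_total"].sum() / frame["sense_total"].sum()
        )
        if frame["sense_total"].sum() > 0
        else np.nan,
    }
    return frame, summary


# ------------------------------------------------------------ lnc neighbors


def find_neighbor_pairs(
    catalog: TranscriptCatalog, max_distance: int = 100_000
) -> pd.DataFrame:
    """Geometry of lncRNA / coding-gene pairs within ``max_distance``.

    Distance anchors: when the lncRNA lies upstream of the coding gene (in the
    coding gene's orientation) the distance is TSS-to-TSS; when downstream, it
    is from the coding gene's 3' end to the nearest point of the lncRNA span.
    Overlapping pairs are skipped.
    """
    lncs = [t for t in catalog if t.major_class == "lncRNA"]
    coding_genes: Dict[str, TranscriptModel] = {}
    for t in catalog:
        if t.major_class == "coding" and t.gene_id not in coding_genes:
            coding_genes[t.gene_id] = t

    rows = []
    for lnc in lncs:
        for gid, rep in coding_genes.items():
            ch = rep.chain
            if ch.chrom != lnc.chain.chrom:
                continue
            if ch.start < lnc.chain.end and lnc.chain.start < ch.end:
                continue  # overlapping; not a neighbor pair
            if ch.strand == "+":
                tss, tes = ch.start, ch.end
                lnc_is_upstream = lnc.chain.end <= tss
            else:
                tss, tes = ch.end, ch.start
                lnc_is_upstream = lnc.chain.start >= tss
            if lnc_is_upstream:
                lnc_tss = lnc.chain.start if lnc.chain.strand == "+" else lnc.chain.end
                distance = abs(tss - lnc_tss)
                position = "upstream"
            else:
                distance = min(abs(tes - lnc.chain.start), abs(tes - lnc.chain.end))
                position = "downstream"
            if distance > max_distance:
                continue
            rows.append(
                {
                    "lnc_id": lnc.transcript_id,
                    "gene_id": gid,
                    "distance": int(distance),
                    "position": position,
                    "strand_relation": "same" if lnc.chain.strand == ch.strand else "opposite",
                }
            )
    return pd.DataFrame(rows, columns=["lnc_id", "gene_id", "distance", "position", "strand_relation"])


def neighbor_correlation(
    catalog: TranscriptCatalog,
    lnc_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    groups: Mapping[str, str],
    spec: NeighborBinSpec = NeighborBinSpec(),
    seed: int = 0,
) -> Tuple[pd.DataFrame, float, pd.DataFrame]:
    """Binned mean combined correlation of lncRNA-coding neighbor pairs.

    ``lnc_expr`` is lncRNA-transcript x sample normalized counts; ``gene_expr``
    is coding-gene x sample.  Returns (binned frame, random-pair baseline,
    per-pair frame).  Bins with no pairs are reported with n=0 and NaN mean
    (missing, not zero).
    """
    pairs = find_neighbor_pairs(catalog, spec.max_distance)
    cols = list(gene_expr.columns)
    labels = [groups[s] for s in cols]
    llog = _log_expr(lnc_expr[cols])
    glog = _log_expr(gene_expr[cols])

    rvals = []
    for row in pairs.itertuples(index=False):
        if row.lnc_id not in llog.index or row.gene_id not in glog.index:
            rvals.append(np.nan)
            continue
        rec = combine_correlation(
            llog.loc[row.lnc_id].values, glog.loc[row.gene_id].values, labels
        )
        rvals.append(rec.r_combined if rec.valid else np.nan)
    pairs = pairs.assign(r_combined=rvals)

    edges = list(spec.bin_edges)
    labels_bins = [f"[{edges[i]}, {edges[i+1]})" for i in range(len(edges) - 1)]
    binned_rows = []
    for position in ("upstream", "downstream"):
        for rel in ("same", "opposite"):
            sub = pairs[(pairs["position"] == position) & (pairs["strand_relation"] == rel)]
            for i in range(len(edges) - 1):
                lo, hi = edges[i], edges[i + 1]
                inclusive = hi == edges[-1]
                m = (sub["distance"] >= lo) & (
                    (sub["distance"] <= hi) if inclusive else (sub["distance"] < hi)
                )
                vals = sub.loc[m, "r_combined"].dropna()
                binned_rows.append(
                    {
                        "position": position,
                        "strand_relation": rel,
                        "bin": labels_bins[i],
                        "bin_lo": lo,
                        "bin_hi": hi,
                        "n": int(len(vals)),
                        "mean_r": float(vals.mean()) if len(vals) else np.nan,
                        "se_r": float(vals.std(ddof=1) / np.sqrt(len(vals)))
                        if len(vals) > 1
                        else np.nan,
                    }
                )
    binned = pd.DataFrame(binned_rows)

    rng = np.random.default_rng(seed)
    lnc_ids = list(llog.index)
    gene_ids = list(glog.index)
    baseline_vals = []
    for _ in range(spec.n_random_pairs):
        li = lnc_ids[rng.integers(len(lnc_ids))]
        gi = gene_ids[rng.integers(len(gene_ids))]
        rec = combine_correlation(llog.loc[li].values, glog.loc[gi].values, labels)
        if rec.valid:
            baseline_vals.append(rec.r_combined)
    baseline = float(np.mean(baseline_vals)) if baseline_vals else np.nan
    return binned, baseline, pairs


# ------------------------------------------------------------- target sets


def target_set_shift(
    target_lists: Mapping[str, Sequence[str]],
    statistic: pd.Series,
    min_list_size: int = 5,
) -> pd.DataFrame:
    """Mean +/- SE of a per-gene statistic over each target list vs background.

    ``statistic`` maps gene id -> value (e.g. adjusted log2 fold change or a
    combined correlation).  The background for each list is every measurable
    gene not in that list.  p is a two-sided Wilcoxon rank-sum test of list vs
    background; lists with fewer than ``min_list_size`` measurable genes are
    flagged low-power (p still reported when computable).
    """
    statistic = statistic.dropna()
    rows = []
    for name, genes in target_lists.items():
        in_list = statistic.index.isin(set(genes))
        vals = statistic[in_list]
        background = statistic[~in_list]
        if len(background) == 0:
            raise ValueError(f"target list {name!r}: empty background")
        n = len(vals)
        p = (
            float(stats.mannwhitneyu(vals, background, alternative="two-sided").pvalue)
            if n >= 1
            else np.nan
        )
        rows.append(
            {
                "list": name,
                "n": n,
                "mean": float(vals.mean()) if n else np.nan,
                "se": float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
                "background_mean": float(background.mean()),
                "background_n": len(background),
                "p": p,
                "low_power": n < min_list_size,
            }
        )
    return pd.DataFrame(rows).set_index("list")
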