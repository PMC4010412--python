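"""Differential transcription between two groups of libraries.

The chain is: expression filter -> total-count normalization (equal amount of
total RNA) -> loess fold-change bias adjustment -> negative-binomial exact test
with a common dispersion -> Benjamini-Hochberg FDR; plus class-level percent
changes of pooled normalized totals.

The exact test conditions on the pooled total of the two groups after library
sizes are equalized.  With counts summed within groups (sums of n iid
NB(mean mu, dispersion phi) variables are NB(mean n*mu, dispersion phi/n)),
the null conditional law of the group-A sum given the grand total is a
negative hypergeometric with shape parameters r_A = n_A/phi, r_B = n_B/phi;
the two-sided p-value sums the probabilities of all outcomes no more probable
than the observed split.  At phi = 0 this degenerates to an exact binomial
split with success probability n_A/(n_A+n_B), which is computed with exact
integer arithmetic.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import math

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .catalog import TranscriptCatalog

_TIE_REL_TOL = 1e-7  # near-tie tolerance on float probabilities (phi > 0 branch)


@dataclass(frozen=True)
class ExpressionFilter:
    min_reads: int = 3
    min_samples: int = 3

    def __post_init__(self):
        if self.min_reads <= 0 or self.min_samples <= 0:
            raise ValueError("expression filter thresholds must be positive integers")


@dataclass(frozen=True)
class ClassChange:
    rna_class: str
    percent_change: float  # pooled_case / pooled_control - 1, on normalized counts
    p: float
    pooled_control: float
    pooled_case: float


def filter_expressed(counts: pd.DataFrame, filt: ExpressionFilter = ExpressionFilter()) -> pd.Index:
    """Ids with at least ``min_reads`` raw counts in at least ``min_samples`` samples."""
    keep = (counts >= filt.min_reads).sum(axis=1) >= filt.min_samples
    return counts.index[keep]


def normalize_totals(counts: pd.DataFrame) -> Tuple[pd.DataFrame, pd.Series]:
    """Scale every sample to the mean library total; returns (normalized, factors)."""
    totals = counts.sum(axis=0).astype(float)
    if (totals == 0).any():
        raise ValueError("cannot normalize a sample with zero total counts")
    factors = totals.mean() / totals
    return counts * factors, factors


def loess_adjust(
    log2fc: pd.Series, baseline: pd.Series, span: float = 0.5
) -> Tuple[pd.Series, pd.Series]:
    """Remove the fold-change-vs-baseline trend by loess.

    ``baseline`` must be on a log scale (e.g. log10(mean+1)).  Returns
    (adjusted log2fc, fitted trend).  Requires at least 50 ids so the local
    regression has support.
    """
    if len(log2fc) < 50:
        raise ValueError(f"loess adjustment needs >= 50 ids, got {len(log2fc)}")
    if not log2fc.index.equals(baseline.index):
        baseline = baseline.loc[log2fc.index]
    trend = lowess(
        log2fc.values, baseline.values, frac=span, it=2, return_sorted=False
    )
    trend = pd.Series(trend, index=log2fc.index)
    return log2fc - trend, trend


# ------------------------------------------------------------- NB exact test


def _exact_p_binomial(s_a: int, s_b: int, n_a: int, n_b: int) -> float:
    """phi = 0: exact binomial split with probability n_a/(n_a+n_b), integer arithmetic."""
    t = s_a + s_b
    if t == 0:
        return 1.0
    # numerator of P(k) with common denominator (n_a+n_b)^t
    weights = [math.comb(t, k) * n_a**k * n_b ** (t - k) for k in range(t + 1)]
    obs = weights[s_a]
    tail = sum(w for w in weights if w <= obs)
    return min(1.0, tail / (n_a + n_b) ** t)


def _exact_p_nb(s_a: int, s_b: int, n_a: int, n_b: int, phi: float) -> float:
    """phi > 0: negative hypergeometric conditional law, float log-space."""
    t = s_a + s_b
    if t == 0:
        return 1.0
    r_a = n_a / phi
    r_b = n_b / phi
    k = np.arange(t + 1)
    logw = (
        gammaln(k + r_a)
        - gammaln(k + 1)
        + gammaln(t - k + r_b)
        - gammaln(t - k + 1)
    )
    logw -= logsumexp(logw)
    w = np.exp(logw)
    obs = w[s_a]
    return float(min(1.0, w[w <= obs * (1.0 + _TIE_REL_TOL)].sum()))


def nb_exact_test(
    counts_a: Sequence[float],
    counts_b: Sequence[float],
    dispersion: float,
) -> float:
    """Two-sided exact test for equal group means of negative-binomial counts.

    ``counts_a`` / ``counts_b`` are per-sample counts with already-equalized
    library sizes (pass normalized pseudo-counts); they are summed within each
    group and rounded to integers.  ``dispersion`` is phi in
    var = mu + phi*mu^2.  All-zero input returns p = 1 by convention.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    n_a, n_b = len(a), len(b)
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups need at least one (pseudo-)sample")
    s_a = int(round(a.sum()))
    s_b = int(round(b.sum()))
    if dispersion == 0:
        if s_a + s_b <= 10_000:
            return _exact_p_binomial(s_a, s_b, n_a, n_b)
        # large totals: float binomial with the same tie rule as the NB branch
        t = s_a + s_b
        k = np.arange(t + 1)
        logw = stats.binom.logpmf(k, t, n_a / (n_a + n_b))
        w = np.exp(logw - logsumexp(logw))
        obs = w[s_a]
        return float(min(1.0, w[w <= obs * (1.0 + _TIE_REL_TOL)].sum()))
    return _exact_p_nb(s_a, s_b, n_a, n_b, dispersion)


def estimate_common_dispersion(
    counts: pd.DataFrame, groups: Mapping[str, str]
) -> float:
    """Moment-based common dispersion phi in var = mu + phi*mu^2.

    Counts should be normalized to equal totals.  Within each group, per-
    transcript sample mean m and variance v satisfy E[v - m] = phi*mu^2, and
    m^2 - v/n is unbiased for mu^2; pooling over transcripts and groups gives
    phi_hat = sum(v - m) / sum(m^2 - v/n), clipped at 0.
    """
    labels = pd.Series({s: groups[s] for s in counts.columns})
    by_group = {g: counts.loc[:, labels[labels == g].index] for g in set(labels)}
    if any(sub.shape[1] < 2 for sub in by_group.values()):
        raise ValueError(
            "dispersion estimation needs >= 2 samples per group; supply phi explicitly"
        )
    num = 0.0
    den = 0.0
    for sub in by_group.values():
        n = sub.shape[1]
        m = sub.mean(axis=1).values
        v = sub.var(axis=1, ddof=1).values
        ok = m > 0
        num += float(np.sum(v[ok] - m[ok]))
        den += float(np.sum(m[ok] ** 2 - v[ok] / n))
    if den <= 0:
        return 0.0
    return max(0.0, num / den)


def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = np.asarray(p, dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# --------------------------------------------------------------- DE pipeline


def de_table(
    counts: pd.DataFrame,
    groups: Mapping[str, str],
    dispersion: Optional[float] = None,
    filt: ExpressionFilter = ExpressionFilter(),
    span: float = 0.5,
    adjust: bool = True,
) -> pd.DataFrame:
    """Full differential-transcription table for a counts matrix.

    Returns one row per retained id with columns mean_control, mean_case,
    log2fc (loess-adjusted when ``adjust``), raw_log2fc, p, q.  Group labels
    are 'control' / 'case'.  When ``dispersion`` is None a common dispersion
    is estimated from the normalized counts.
    """
    keep = filter_expressed(counts, filt)
    counts = counts.loc[keep]
    norm, _ = normalize_totals(counts)
    ctrl_cols = [s for s in norm.columns if groups[s] == "control"]
    case_cols = [s for s in norm.columns if groups[s] == "case"]
    if not ctrl_cols or not case_cols:
        raise ValueError("both 'control' and 'case' groups must be non-empty")

    mean_ctrl = norm[ctrl_cols].mean(axis=1)
    mean_case = norm[case_cols].mean(axis=1)
    raw_lfc = np.log2((mean_case + 0.5) / (mean_ctrl + 0.5))
    baseline = np.log10(norm.mean(axis=1) + 1.0)
    if adjust:
        lfc, _ = loess_adjust(raw_lfc, baseline, span=span)
    else:
        lfc = raw_lfc

    if dispersion is None:
        dispersion = estimate_common_dispersion(norm, groups)

    pseudo = norm.round().astype(int)
    pvals = np.empty(len(pseudo))
    a = pseudo[ctrl_cols].values
    b = pseudo[case_cols].values
    for i in range(len(pseudo)):
        pvals[i] = nb_exact_test(a[i], b[i], dispersion)
    q = bh_fdr(pvals)

    return pd.DataFrame(
        {
            "mean_control": mean_ctrl,
            "mean_case": mean_case,
            "log2fc": lfc,
            "raw_log2fc": raw_lfc,
            "p": pvals,
            "q": q,
        },
        index=counts.index,
    )


def class_change(
    norm_counts: pd.DataFrame,
    catalog: TranscriptCatalog,
    rna_class: str,
    groups: Mapping[str, str],
) -> ClassChange:
    """Percent change of a class's pooled normalized totals, case vs control.

    The p-value is a two-sided Welch t-test comparing per-sample class
    proportions (class total / sample total) between the groups; this is a
    deliberately conservative choice under NB overdispersion, in place of a
    pooled-count binomial test.
    """
    members = [t.transcript_id for t in catalog.by_class(rna_class)]
    members = [t for t in members if t in norm_counts.index]
    if not members:
        raise ValueError(f"class {rna_class!r} has no members in the counts matrix")
    ctrl_cols = [s for s in norm_counts.columns if groups[s] == "control"]
    case_cols = [s for s in norm_counts.columns if groups[s] == "case"]
    class_totals = norm_counts.loc[members].sum(axis=0)
    sample_totals = norm_counts.sum(axis=0)
    pooled_ctrl = float(class_totals[ctrl_cols].sum())
    pooled_case = float(class_totals[case_cols].sum())
    # pooled totals are per-group sums; put them on a per-sample scale first
    pct = (pooled_case / len(case_cols)) / (pooled_ctrl / len(ctrl_cols)) - 1.0
    prop = class_totals / sample_totals
    p = float(
        stats.ttest_ind(prop[ctrl_cols], prop[case_cols], equal_var=False).pvalue
    )
    return ClassChange(
        rna_class=rna_class,
        percent_change=pct,
        p=p,
        pooled_control=pooled_ctrl,
        pooled_case=pooled_case,
    )
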