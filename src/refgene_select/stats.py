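"""Per-gene descriptive statistics: mean, variance, SD and CV across samples.

The coefficient of variation (CV = sd / mean) is the pipeline's primary
stability statistic: a candidate reference gene should combine a high mean
read count with a low CV across all samples. This module computes the
per-gene statistics table, five-number summaries, Pearson relationships among
the statistics, and the CV ranking of candidates.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import CountMatrix, ValidationError

logger = logging.getLogger("refgene_select")

STAT_COLUMNS = ["total", "mean", "variance", "sd", "cv"]


def gene_stats(counts: CountMatrix, ddof: int = 1) -> pd.DataFrame:
    """Per-gene total, mean, variance, SD and CV across samples.

    Totals are summed in integer arithmetic before division, so
    ``mean * n_samples == total`` exactly. Variance uses the sample (n-1)
    denominator by default (``ddof`` exposed for the population convention).
    A gene with mean 0 is retained with its CV flagged undefined (NaN).
    """
    if counts.n_samples < 2:
        raise ValidationError("gene statistics need >= 2 samples")
    x = counts.counts.to_numpy()
    total = x.sum(axis=1, dtype=np.int64)
    mean = total / counts.n_samples
    variance = x.var(axis=1, ddof=ddof)
    sd = np.sqrt(variance)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    if (mean == 0).any():
        logger.warning("%d gene(s) with mean 0: CV undefined", int((mean == 0).sum()))
    return pd.DataFrame(
        {"total": total, "mean": mean, "variance": variance, "sd": sd, "cv": cv},
        index=counts.counts.index.rename("gene_id"),
    )


def describe(stats: pd.DataFrame) -> pd.DataFrame:
    """Five-number summary (min, q1, median, q3, max) of mean, variance, CV.

    Quartiles use linear interpolation between order statistics.
    """
    if len(stats) < 1:
        raise ValidationError("describe needs at least one gene")
    rows = {}
    for col in ("mean", "variance", "cv"):
        v = stats[col].dropna().to_numpy()
        rows[col] = {
            "min": np.min(v),
            "q1": np.quantile(v, 0.25),
            "median": np.quantile(v, 0.5),
            "q3": np.quantile(v, 0.75),
            "max": np.max(v),
        }
    return pd.DataFrame(rows).T[["min", "q1", "median", "q3", "max"]]


def significance_code(p: float) -> str:
    """Conventional star codes: *** p<0.001, ** p<0.01, * p<0.05, else n.s."""
    if np.isnan(p):
        return "undef"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


def stat_correlations(stats: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations among per-gene mean, variance and CV.

    Two-sided p-values use the exact t transform t = r sqrt(n-2)/sqrt(1-r^2).
    A statistic constant across genes gets its pairs flagged undefined.
    Returns a long-form table with columns ``stat_a, stat_b, r, p, code``.
    """
    if len(stats) < 3:
        raise ValidationError("correlations need >= 3 genes")
    cols = ("mean", "variance", "cv")
    sub = stats.loc[:, cols].dropna()
    records = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            xa, xb = sub[a].to_numpy(), sub[b].to_numpy()
            if np.ptp(xa) == 0 or np.ptp(xb) == 0:
                logger.warning("correlation %s~%s undefined: zero variance", a, b)
                r, p = np.nan, np.nan
            else:
                r, p = sps.pearsonr(xa, xb)
            records.append(
                {"stat_a": a, "stat_b": b, "r": r, "p": p, "code": significance_code(p)}
            )
    return pd.DataFrame.from_records(records)


def rank_by_cv(stats: pd.DataFrame) -> pd.DataFrame:
    """Rank genes by ascending CV (most stable first).

    Ties are broken by descending mean, then gene id, so the output is
    deterministic. Genes with undefined CV are excluded with a warning.
    """
    defined = stats[stats["cv"].notna()].copy()
    dropped = len(stats) - len(defined)
    if dropped:
        logger.warning("excluding %d gene(s) with undefined CV from ranking", dropped)
    tmp = defined.reset_index()
    id_col = tmp.columns[0]
    tmp = tmp.sort_values(by=["cv", "mean", id_col], ascending=[True, False, True],
                          kind="mergesort")
    ranked = tmp.set_index(id_col)
    ranked.insert(0, "rank", np.arange(1, len(ranked) + 1))
    return ranked
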