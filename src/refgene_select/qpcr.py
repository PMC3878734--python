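"""qPCR support computations: standard curves, Ct variability, relative expression.

The amplification efficiency E of a primer pair is estimated from a dilution
series: ordinary least squares of Ct on log10 input quantity gives a slope
b (< 0 for a valid curve), and E = 10^(-1/b) - 1; a slope of -3.3219 means
perfect doubling (E = 100%). Panels are conventionally accepted when E falls
within 83-110%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import CtTable, ValidationError

logger = logging.getLogger("refgene_select")

#: inclusive acceptance band for amplification efficiency
EFFICIENCY_RANGE = (0.83, 1.10)


@dataclass
class StandardCurve:
    """Fitted dilution-series curve: Ct = intercept + slope * log10(quantity)."""

    log10_quantity: np.ndarray
    mean_ct: np.ndarray
    slope: float
    intercept: float
    r_squared: float
    efficiency: float

    @property
    def efficiency_percent(self) -> float:
        return 100.0 * self.efficiency


def fit_standard_curve(log10_quantity: np.ndarray, ct: np.ndarray) -> StandardCurve:
    """OLS standard curve and amplification efficiency from a dilution series.

    Requires >= 3 distinct dilution points and a negative slope
    (Ct decreases with template amount); E = 10^(-1/slope) - 1.
    """
    x = np.asarray(log10_quantity, dtype=float)
    y = np.asarray(ct, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("log10_quantity and ct must have the same length")
    if len(np.unique(x)) < 3:
        raise ValidationError("standard curve needs >= 3 distinct dilution points")
    fit = sps.linregress(x, y)
    if fit.slope >= 0:
        raise ValidationError("invalid standard curve: non-negative slope")
    efficiency = 10.0 ** (-1.0 / fit.slope) - 1.0
    return StandardCurve(
        log10_quantity=x, mean_ct=y,
        slope=float(fit.slope), intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2), efficiency=float(efficiency),
    )


def efficiency_check(efficiency: float) -> str:
    """Flag an amplification efficiency against the 83-110% acceptance band.

    Returns ``"in_range"`` for 0.83 <= E <= 1.10 (inclusive), else
    ``"out_of_range"``.
    """
    if efficiency < 0:
        raise ValidationError("efficiency must be >= 0")
    lo, hi = EFFICIENCY_RANGE
    return "in_range" if lo <= efficiency <= hi else "out_of_range"


def ct_variability(ct: CtTable, ddof: int = 1) -> pd.DataFrame:
    """Per-gene five-number summary and CV of raw Ct values.

    Quartiles use linear interpolation (same convention as the count-level
    descriptive statistics). Genes with every Ct missing are excluded with a
    warning; genes need >= 2 observed values.
    """
    frame = ct.ct
    n_obs = frame.notna().sum(axis=1)
    empty = n_obs == 0
    if empty.any():
        logger.warning("excluding all-missing gene(s): %s", list(frame.index[empty]))
        frame = frame[~empty]
        n_obs = n_obs[~empty]
    if (n_obs < 2).any():
        raise ValidationError(
            f"genes with < 2 Ct values: {list(frame.index[n_obs < 2])}"
        )
    rows = {}
    for gene, row in frame.iterrows():
        v = row.dropna().to_numpy()
        mean = v.mean()
        sd = v.std(ddof=ddof)
        rows[gene] = {
            "min": np.min(v),
            "q1": np.quantile(v, 0.25),
            "median": np.quantile(v, 0.5),
            "q3": np.quantile(v, 0.75),
            "max": np.max(v),
            "cv": sd / mean if mean != 0 else np.nan,
        }
    out = pd.DataFrame(rows).T
    out.index.name = "gene_id"
    return out


def relative_expression(q: pd.DataFrame, groups: pd.Series,
                        reference_gene: str | None = None) -> pd.DataFrame:
    """Per-gene, per-group mean quantity and SE, scaled to the lowest group.

    Each gene's group means are divided by its minimum group mean so the
    lowest-expressing group reads 1; SEs are scaled identically. If
    ``reference_gene`` is given, quantities are first normalized sample-wise
    by that gene (ratio-to-reference reading) before group summaries.

    Returns a long-form table with columns ``gene_id, group, mean, se``.
    """
    if (q.to_numpy() <= 0).any():
        raise ValidationError("quantities must be strictly positive")
    groups = groups.reindex(q.columns)
    if groups.isna().any():
        raise ValidationError("every sample needs a group label")
    if reference_gene is not None:
        if reference_gene not in q.index:
            raise ValidationError(f"reference gene {reference_gene!r} not in matrix")
        q = q.div(q.loc[reference_gene], axis=1)
    records = []
    for gene, row in q.iterrows():
        by_group = row.groupby(groups)
        means = by_group.mean()
        if (by_group.size() == 0).any():
            raise ValidationError("empty group")
        ses = by_group.std(ddof=1) / np.sqrt(by_group.size())
        scale = means.min()
        for g in means.index:
            records.append({"gene_id": gene, "group": g,
                            "mean": means[g] / scale,
                            "se": (ses[g] / scale) if np.isfinite(ses[g]) else np.nan})
    return pd.DataFrame.from_records(records)
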