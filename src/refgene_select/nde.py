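"""Non-differentially-expressed (NDE) gene filtering across condition pairs.

A candidate reference gene must show no evidence of differential expression
in ANY pairwise comparison between experimental conditions and must be
detectably expressed (at least ``min_reads_per_sample`` reads) in every
sample. The differential-expression test here is an exact conditional
binomial test on group-summed counts: conditional on the total count of a
gene in the two groups, under the null the group-A sum is Binomial(n, p0)
with p0 = group A's share of the total size factors. Overdispersion is
handled by a quasi-likelihood variance inflation 1 + phi * mbar that shrinks
the observed deviation from its null expectation before the exact test; with
phi = 0 the test reduces exactly to the classical two-sided binomial test.

Externally computed per-comparison p-values (e.g. from a dedicated DE
package) can be supplied instead via ``select_nde(..., external_pvalues=)``.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_array, check_is_fitted
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix, RunConfig, ValidationError
from .stats import gene_stats

logger = logging.getLogger("refgene_select")


@dataclass
class DEResult:
    """One gene x comparison differential-expression record."""

    gene_id: str
    comparison: tuple[str, str]
    p_value: float
    adjusted_p: float


def size_factors(counts: CountMatrix) -> pd.Series:
    """Total-count size factors scaled to geometric mean 1."""
    libsize = counts.counts.sum(axis=0).astype(float)
    if (libsize <= 0).any():
        raise ValidationError("every sample needs a positive library size")
    return libsize / np.exp(np.log(libsize).mean())


def estimate_dispersion(counts_for_gene: np.ndarray, size_factors: np.ndarray) -> float:
    """Method-of-moments NB dispersion on size-factor-scaled counts.

    phi = max(0, (s^2 - mbar) / mbar^2) with mbar the scaled mean and s^2 the
    scaled sample variance; 0 for Poisson-or-under-dispersed genes.
    """
    y = np.asarray(counts_for_gene, dtype=float)
    sf = np.asarray(size_factors, dtype=float)
    if y.size < 2:
        raise ValidationError("dispersion needs >= 2 observations")
    if (sf <= 0).any():
        raise ValidationError("size factors must be positive")
    scaled = y / sf
    mbar = scaled.mean()
    if mbar == 0:
        logger.warning("all-zero gene: dispersion set to 0")
        return 0.0
    s2 = scaled.var(ddof=1)
    return max(0.0, (s2 - mbar) / mbar**2)


def _binom_p_two_sided(k: int, n: int, p0: float) -> float:
    if n == 0:
        return 1.0
    return sps.binomtest(k, n, p0, alternative="two-sided").pvalue


def pairwise_de_test(
    counts: CountMatrix,
    group_a: list[str],
    group_b: list[str],
    alpha: float = 0.05,
    dispersion: float | np.ndarray | None = None,
) -> list[DEResult]:
    """Exact conditional binomial DE test between two sample groups.

    Parameters
    ----------
    group_a, group_b
        Disjoint, non-empty lists of sample ids.
    dispersion
        NB dispersion phi used for the quasi-likelihood inflation
        1 + phi * mbar. ``None`` (default) estimates it per gene by the
        within-group moment estimator; a scalar or per-gene array fixes it.

    Returns one :class:`DEResult` per gene, Benjamini-Hochberg adjusted
    across genes.
    """
    ga, gb = list(group_a), list(group_b)
    if not ga or not gb:
        raise ValidationError("both groups must be non-empty")
    if set(ga) & set(gb):
        raise ValidationError("groups must be disjoint")
    sf = size_factors(counts)
    sf_a, sf_b = sf[ga].to_numpy(), sf[gb].to_numpy()
    tot_a, tot_b = sf_a.sum(), sf_b.sum()
    if tot_a <= 0 or tot_b <= 0:
        raise ValidationError("a group has zero total size factor")
    p0 = tot_a / (tot_a + tot_b)

    xa = counts.counts[ga].to_numpy()
    xb = counts.counts[gb].to_numpy()
    n_genes = counts.n_genes

    if dispersion is None:
        phi = np.empty(n_genes)
        w_a, w_b = len(ga) - 1, len(gb) - 1
        for i in range(n_genes):
            parts, weights = [], []
            if w_a > 0:
                parts.append(estimate_dispersion(xa[i], sf_a))
                weights.append(w_a)
            if w_b > 0:
                parts.append(estimate_dispersion(xb[i], sf_b))
                weights.append(w_b)
            phi[i] = np.average(parts, weights=weights) if parts else 0.0
        # moment estimates from small groups are noisy enough to fatten the
        # null tail; shrink toward the across-gene median (prior df 20)
        if n_genes >= 3:
            d, d0 = max(w_a + w_b, 1), 20.0
            phi = (d * phi + d0 * np.median(phi)) / (d + d0)
    else:
        phi = np.broadcast_to(np.asarray(dispersion, dtype=float), (n_genes,))

    scaled_mean = (counts.counts[ga + gb].to_numpy() / sf[ga + gb].to_numpy()).mean(axis=1)
    inflation = 1.0 + phi * scaled_mean

    pvals = np.empty(n_genes)
    for i in range(n_genes):
        a = int(xa[i].sum())
        n = a + int(xb[i].sum())
        # quasi-likelihood widening: shrink the deviation from the null mean
        # by sqrt(1 + phi*mbar); identity when phi = 0
        k = int(round(n * p0 + (a - n * p0) / np.sqrt(inflation[i])))
        k = min(max(k, 0), n)
        pvals[i] = _binom_p_two_sided(k, n, p0)

    adjusted = multipletests(pvals, method="fdr_bh")[1]
    comparison = ("|".join(ga), "|".join(gb))
    return [
        DEResult(gene_id=g, comparison=comparison, p_value=float(p), adjusted_p=float(q))
        for g, p, q in zip(counts.gene_ids, pvals, np.maximum(adjusted, pvals))
    ]


def condition_comparisons(counts: CountMatrix) -> list[tuple[str, str]]:
    """All unordered pairs of distinct condition labels in the design."""
    labels = sorted(counts.condition_labels().unique())
    return list(itertools.combinations(labels, 2))


def select_nde(
    counts: CountMatrix,
    cfg: RunConfig,
    dispersion: float | np.ndarray | None = None,
    external_pvalues: pd.DataFrame | None = None,
) -> set[str]:
    """Genes non-DE in every pairwise condition comparison, expressed
    everywhere, and (optionally) below a CV cap.

    A gene is kept iff (a) its BH-adjusted p is >= ``cfg.alpha`` in EVERY
    pairwise comparison of condition labels, (b) it has at least
    ``cfg.min_reads_per_sample`` reads in every sample, and (c) when
    ``cfg.max_cv`` is set, its CV does not exceed it.

    ``external_pvalues`` replaces the built-in test: a long-form DataFrame
    with columns ``gene_id, comparison, adjusted_p`` (one row per gene per
    comparison).
    """
    cond = counts.condition_labels()
    if cond.nunique() < 2:
        raise ValidationError("NDE filtering needs >= 2 conditions in the design")

    keep = pd.Series(True, index=counts.counts.index)

    if external_pvalues is not None:
        required = {"gene_id", "comparison", "adjusted_p"}
        if not required <= set(external_pvalues.columns):
            raise ValidationError(f"external p-value table needs columns {sorted(required)}")
        min_adj = external_pvalues.groupby("gene_id")["adjusted_p"].min()
        keep &= min_adj.reindex(keep.index).fillna(0.0) >= cfg.alpha
        n_comparisons = external_pvalues["comparison"].nunique()
    else:
        pairs = condition_comparisons(counts)
        n_comparisons = len(pairs)
        for cond_a, cond_b in pairs:
            ga = list(cond.index[cond == cond_a])
            gb = list(cond.index[cond == cond_b])
            results = pairwise_de_test(counts, ga, gb, alpha=cfg.alpha,
                                       dispersion=dispersion)
            adj = pd.Series({r.gene_id: r.adjusted_p for r in results})
            keep &= adj.reindex(keep.index) >= cfg.alpha
    logger.info("NDE test over %d pairwise comparisons", n_comparisons)

    keep &= (counts.counts >= cfg.min_reads_per_sample).all(axis=1)

    if cfg.max_cv is not None:
        st = gene_stats(counts)
        keep &= st["cv"].fillna(np.inf) <= cfg.max_cv

    selected = set(keep.index[keep])
    logger.info("NDE filter kept %d / %d genes", len(selected), counts.n_genes)
    return selected


class NDEFilter(SelectorMixin, BaseEstimator):
    """Feature selector keeping non-differentially-expressed genes.

    Scikit-learn convention: ``X`` is samples x genes; ``y`` gives the
    per-sample condition label. After ``fit``, ``get_support()`` masks the
    retained genes.

    Parameters
    ----------
    alpha : float, default 0.05
        Per-comparison BH-adjusted significance level; a gene is dropped if
        significant in any comparison.
    min_reads_per_sample : int, default 100
        Expression floor applied to every sample.
    max_cv : float or None, default None
        Optional variation-index cap across samples.
    dispersion : float, array or None, default None
        Fixed NB dispersion for the test; None = per-gene moment estimate.
    """

    def __init__(self, alpha: float = 0.05, min_reads_per_sample: int = 100,
                 max_cv: float | None = None,
                 dispersion: float | np.ndarray | None = None):
        self.alpha = alpha
        self.min_reads_per_sample = min_reads_per_sample
        self.max_cv = max_cv
        self.dispersion = dispersion

    def fit(self, X, y):
        """Fit on a samples x genes count matrix with condition labels y."""
        gene_names = list(X.columns) if isinstance(X, pd.DataFrame) else None
        X = check_array(X, dtype="numeric", ensure_min_samples=2)
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValidationError("y must give one condition label per sample")
        self.n_features_in_ = X.shape[1]
        if gene_names is None:
            gene_names = [f"g{i}" for i in range(X.shape[1])]
        else:
            self.feature_names_in_ = np.asarray(gene_names, dtype=object)
        cm = CountMatrix(
            counts=pd.DataFrame(
                X.T.astype(np.int64), index=gene_names,
                columns=[f"s{i}" for i in range(X.shape[0])],
            ),
            design=pd.DataFrame(
                {"genotype": "NA", "stage": y.astype(str), "treatment": "NA"},
                index=[f"s{i}" for i in range(X.shape[0])],
            ),
        )
        cfg = RunConfig(alpha=self.alpha, min_reads_per_sample=self.min_reads_per_sample,
                        max_cv=self.max_cv)
        selected = select_nde(cm, cfg, dispersion=self.dispersion)
        self.support_ = np.array([g in selected for g in gene_names])
        self.gene_names_ = np.asarray(gene_names, dtype=object)
        self.selected_genes_ = [g for g in gene_names if g in selected]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_
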