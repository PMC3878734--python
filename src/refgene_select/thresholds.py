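"""Pseudo-gene resampling and order-statistic thresholds on mean and CV.

The selection rule asks whether a gene's high mean and low CV could have
arisen by chance from the pooled count distribution. To calibrate that, a
null population of "pseudo genes" is built: each pseudo gene is n_samples
read counts drawn uniformly with replacement from ALL entries of the observed
matrix, and its mean and CV are computed exactly as for real genes. Sorting
the 10,000 pseudo means and CVs, the k-th order statistics (k = round(p * N),
e.g. the 9,750-th mean for the 97.5% percentile and the 250-th CV for the
2.5% percentile) become the selection thresholds: a candidate must have mean
strictly above the mean threshold AND CV strictly below the CV threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .io import CountMatrix, RunConfig, ValidationError, child_seed

logger = logging.getLogger("refgene_select")


@dataclass
class PseudoGeneSet:
    """Means and CVs of resampled pseudo genes (the null population)."""

    means: np.ndarray
    cvs: np.ndarray
    source_shape: tuple[int, int]
    seed: int

    @property
    def n_pseudo(self) -> int:
        return len(self.means)


@dataclass
class ThresholdResult:
    """Thresholds for one percentile pair and the genes passing both."""

    cv_percentile: float
    mu_percentile: float
    cv_threshold: float
    mu_threshold: float
    selected: list[str]

    @property
    def n_selected(self) -> int:
        return len(self.selected)


def simulate_pseudo_genes(counts: CountMatrix, n_pseudo: int = 10_000,
                          seed: int = 0) -> PseudoGeneSet:
    """Simulate pseudo genes by pooled resampling of the count matrix.

    Each pseudo gene is ``n_samples`` values drawn uniformly with replacement
    from the pooled set of all matrix entries; its mean and CV (sample SD /
    mean) are recorded. Reproducible given the seed.
    """
    if n_pseudo < 1:
        raise ValidationError("n_pseudo must be >= 1")
    pool = counts.counts.to_numpy().ravel()
    n_samples = counts.n_samples
    rng = np.random.default_rng(child_seed(seed, "simulate_pseudo_genes"))
    draws = rng.choice(pool, size=(n_pseudo, n_samples), replace=True).astype(float)
    means = draws.mean(axis=1)
    sds = draws.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cvs = np.where(means > 0, sds / means, np.nan)
    return PseudoGeneSet(means=means, cvs=cvs,
                         source_shape=(counts.n_genes, n_samples), seed=seed)


def order_statistic_index(percentile: float, n: int) -> int:
    """1-based rank of the order statistic used for a percentile threshold.

    k = round(percentile * n), clamped to [1, n]; at n = 10,000 this gives
    the 9,750-th sorted value for 97.5% and the 250-th for 2.5%.
    """
    if n < 1:
        raise ValidationError("empty pseudo set")
    k = int(round(percentile * n))
    return min(max(k, 1), n)


def percentile_thresholds(pseudo: PseudoGeneSet, cv_percentile: float,
                          mu_percentile: float) -> tuple[float, float]:
    """Order-statistic thresholds (cv_threshold, mu_threshold).

    The mean threshold is the k-th smallest pseudo mean with
    k = round(mu_percentile * N); the CV threshold the k-th smallest pseudo
    CV with k = round(cv_percentile * N).
    """
    if not 0 < cv_percentile < mu_percentile < 1:
        raise ValidationError("need 0 < cv_percentile < mu_percentile < 1")
    n = pseudo.n_pseudo
    if n < 1:
        raise ValidationError("empty pseudo set")
    means = np.sort(pseudo.means)
    cvs = np.sort(pseudo.cvs[~np.isnan(pseudo.cvs)])
    if len(cvs) < 1:
        raise ValidationError("no defined pseudo-gene CVs")
    mu_thr = means[order_statistic_index(mu_percentile, n) - 1]
    cv_thr = cvs[order_statistic_index(cv_percentile, len(cvs)) - 1]
    return float(cv_thr), float(mu_thr)


def select_candidates(stats: pd.DataFrame, thr: tuple[float, float],
                      cv_percentile: float = np.nan,
                      mu_percentile: float = np.nan) -> ThresholdResult:
    """Genes with mean strictly above and CV strictly below the thresholds.

    ``stats`` is the per-gene table from :func:`refgene_select.stats.gene_stats`.
    The result is ordered by ascending CV. Genes exactly on a threshold are
    excluded (strict inequalities) and reported in the log.
    """
    if len(stats) < 1:
        raise ValidationError("no gene statistics provided")
    cv_thr, mu_thr = thr
    mask = (stats["mean"] > mu_thr) & (stats["cv"] < cv_thr)
    boundary = ((stats["mean"] == mu_thr) | (stats["cv"] == cv_thr))
    if boundary.any():
        logger.info("genes on a threshold boundary (excluded): %s",
                    list(stats.index[boundary]))
    chosen = stats[mask].sort_values(["cv", "mean"], ascending=[True, False],
                                     kind="mergesort")
    return ThresholdResult(
        cv_percentile=cv_percentile, mu_percentile=mu_percentile,
        cv_threshold=cv_thr, mu_threshold=mu_thr,
        selected=list(chosen.index),
    )


def threshold_sweep(counts: CountMatrix, stats: pd.DataFrame,
                    cfg: RunConfig) -> list[ThresholdResult]:
    """One ThresholdResult per configured percentile pair.

    All pairs share a single pseudo-gene set, which guarantees nested
    selections: tightening the percentiles can only shrink the selected set.
    """
    pseudo = simulate_pseudo_genes(counts, n_pseudo=cfg.n_pseudo, seed=cfg.seed)
    results = []
    for cv_p, mu_p in cfg.percentile_pairs:
        cv_thr, mu_thr = percentile_thresholds(pseudo, cv_p, mu_p)
        res = select_candidates(stats, (cv_thr, mu_thr),
                                cv_percentile=cv_p, mu_percentile=mu_p)
        logger.info("percentiles (CV %.3g, mu %.3g): thresholds (%.4g, %.4g), "
                    "n_selected=%d", cv_p, mu_p, cv_thr, mu_thr, res.n_selected)
        results.append(res)
    return results


def sweep_table(results: list[ThresholdResult]) -> pd.DataFrame:
    """Flatten a threshold sweep into a report table (one row per pair)."""
    return pd.DataFrame(
        {
            "cv_percentile": [r.cv_percentile for r in results],
            "mu_percentile": [r.mu_percentile for r in results],
            "cv_threshold": [r.cv_threshold for r in results],
            "mu_threshold": [r.mu_threshold for r in results],
            "n_selected": [r.n_selected for r in results],
        }
    )


class CVMeanSelector(SelectorMixin, BaseEstimator):
    """Feature selector keeping high-mean, low-CV genes against a resampled null.

    Scikit-learn convention: ``X`` is samples x genes counts. Fitting builds
    the pooled pseudo-gene null, derives the order-statistic thresholds for
    ``(cv_percentile, mu_percentile)`` and keeps genes with mean strictly
    above the mean threshold and CV strictly below the CV threshold.

    Attributes
    ----------
    cv_threshold_, mu_threshold_ : float
        The derived cutoffs.
    pseudo_ : PseudoGeneSet
        The null population used.
    """

    def __init__(self, cv_percentile: float = 0.025, mu_percentile: float = 0.975,
                 n_pseudo: int = 10_000, random_state: int = 0):
        self.cv_percentile = cv_percentile
        self.mu_percentile = mu_percentile
        self.n_pseudo = n_pseudo
        self.random_state = random_state

    def fit(self, X, y=None):
        from .stats import gene_stats  # local import avoids cycle

        gene_names = list(X.columns) if isinstance(X, pd.DataFrame) else None
        X = check_array(X, dtype="numeric", ensure_min_samples=2)
        self.n_features_in_ = X.shape[1]
        if gene_names is None:
            gene_names = [f"g{i}" for i in range(X.shape[1])]
        else:
            self.feature_names_in_ = np.asarray(gene_names, dtype=object)
        cm = CountMatrix(
            counts=pd.DataFrame(X.T.astype(np.int64), index=gene_names,
                                columns=[f"s{i}" for i in range(X.shape[0])]),
            design=pd.DataFrame({"genotype": "NA", "stage": "NA", "treatment": "NA"},
                                index=[f"s{i}" for i in range(X.shape[0])]),
        )
        self.pseudo_ = simulate_pseudo_genes(cm, n_pseudo=self.n_pseudo,
                                             seed=self.random_state)
        self.cv_threshold_, self.mu_threshold_ = percentile_thresholds(
            self.pseudo_, self.cv_percentile, self.mu_percentile)
        st = gene_stats(cm)
        res = select_candidates(st, (self.cv_threshold_, self.mu_threshold_),
                                self.cv_percentile, self.mu_percentile)
        chosen = set(res.selected)
        self.support_ = np.array([g in chosen for g in gene_names])
        self.gene_names_ = np.asarray(gene_names, dtype=object)
        self.selected_genes_ = [g for g in gene_names if g in chosen]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_
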