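"""geNorm expression-stability ranking with stepwise exclusion.

Given strictly positive relative expression quantities for a panel of
candidate reference genes, the pairwise variation between genes j and k is
V_jk = SD over samples of log2(q_j / q_k); a gene's stability value
M_j is the average of V_jk over all partners k != j. Lower M = more stable.
Ranking proceeds by stepwise exclusion: repeatedly drop the gene with the
highest M and recompute until two genes remain; those two form the final,
unordered most-stable pair (their M values are identical by construction).

Quantities are usually derived from qPCR Ct values through a standard curve:
q = (1 + E)^(Ct_min - Ct) with E the gene's amplification efficiency, so the
sample with the lowest Ct (highest expression) is the calibrator at q = 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .io import CtTable, ValidationError

logger = logging.getLogger("refgene_select")


@dataclass
class StabilityRound:
    """One round of stepwise exclusion."""

    remaining: list[str]
    m_values: dict[str, float]
    excluded: str | None  # None in the final 2-gene round


@dataclass
class StabilityRanking:
    """Full stepwise-exclusion trace and the final most-stable pair."""

    rounds: list[StabilityRound]
    final_pair: tuple[str, str]
    exclusion_order: list[str]

    def m_trace(self) -> pd.DataFrame:
        """Genes x rounds table of M values (NaN after exclusion)."""
        genes = sorted(self.rounds[0].m_values)
        data = {f"round{i + 1}": pd.Series(r.m_values) for i, r in enumerate(self.rounds)}
        return pd.DataFrame(data).reindex(genes)


def _validate_quantities(q: pd.DataFrame) -> pd.DataFrame:
    q = q.astype(float)
    if (q.to_numpy() <= 0).any() or np.isnan(q.to_numpy()).any():
        raise ValidationError("quantities must be strictly positive and finite")
    return q


def pairwise_sd(q: pd.DataFrame, gene_j: str, gene_k: str, ddof: int = 1) -> float:
    """V_jk: SD over samples of the pairwise log2 expression ratio."""
    q = _validate_quantities(q.loc[[gene_j, gene_k]])
    if q.shape[1] < 2:
        raise ValidationError("pairwise variation needs >= 2 samples")
    ratios = np.log2(q.loc[gene_j].to_numpy() / q.loc[gene_k].to_numpy())
    return float(np.std(ratios, ddof=ddof))


def m_value(q: pd.DataFrame, gene_j: str, ddof: int = 1) -> float:
    """Stability M_j: mean pairwise variation of gene_j with all partners."""
    if q.shape[0] < 2:
        raise ValidationError("M needs at least one partner gene")
    return float(np.mean([pairwise_sd(q, gene_j, k, ddof=ddof)
                          for k in q.index if k != gene_j]))


def _all_m_values(q: pd.DataFrame, ddof: int = 1) -> pd.Series:
    """M for every gene at once (vectorised over the pairwise SD matrix)."""
    logq = np.log2(_validate_quantities(q).to_numpy())
    n = logq.shape[0]
    diffs = logq[:, None, :] - logq[None, :, :]  # genes x genes x samples
    v = diffs.std(axis=2, ddof=ddof)
    m = (v.sum(axis=1)) / (n - 1)  # diagonal is 0
    return pd.Series(m, index=q.index)


def stepwise_ranking(q: pd.DataFrame, ddof: int = 1) -> StabilityRanking:
    """Rank genes by stepwise exclusion of the least stable one.

    Each round computes M for the remaining genes and drops the gene with
    the maximal M (ties broken by gene id, logged); stops when two genes
    remain. Returns the full trace.
    """
    q = _validate_quantities(q)
    if q.shape[0] < 3:
        raise ValidationError("stepwise ranking needs >= 3 genes")
    if q.shape[1] < 2:
        raise ValidationError("stepwise ranking needs >= 2 samples")
    remaining = q.copy()
    rounds: list[StabilityRound] = []
    exclusion_order: list[str] = []
    while remaining.shape[0] > 2:
        m = _all_m_values(remaining, ddof=ddof)
        worst = m.max()
        ties = sorted(m.index[m == worst])
        if len(ties) > 1:
            logger.info("M tie among %s: excluding %s", ties, ties[0])
        excluded = ties[0]
        rounds.append(StabilityRound(remaining=list(remaining.index),
                                     m_values=m.to_dict(), excluded=excluded))
        exclusion_order.append(excluded)
        remaining = remaining.drop(index=excluded)
    m = _all_m_values(remaining, ddof=ddof)
    rounds.append(StabilityRound(remaining=list(remaining.index),
                                 m_values=m.to_dict(), excluded=None))
    final_pair = tuple(sorted(remaining.index))
    return StabilityRanking(rounds=rounds, final_pair=final_pair,  # type: ignore[arg-type]
                            exclusion_order=exclusion_order)


def ct_preprocess(ct: CtTable) -> pd.DataFrame:
    """Transform Ct values to relative quantities via the standard curve.

    Per gene, quantity = (1+E)^(Ct_min - Ct): the sample with the lowest Ct
    gets quantity 1. Samples with a missing Ct in any retained gene are
    dropped (geNorm needs a complete matrix); genes with < 2 observed Ct
    values are excluded with a warning.
    """
    frame = ct.ct
    enough = frame.notna().sum(axis=1) >= 2
    if (~enough).any():
        logger.warning("excluding gene(s) with < 2 Ct values: %s",
                       list(frame.index[~enough]))
        frame = frame[enough]
    if frame.empty:
        raise ValidationError("no genes with enough Ct values")
    complete = frame.notna().all(axis=0)
    if (~complete).any():
        logger.warning("dropping sample(s) with missing Ct: %s",
                       list(frame.columns[~complete]))
        frame = frame.loc[:, complete]
    if frame.shape[1] < 2:
        raise ValidationError("fewer than 2 complete samples after dropping missing Ct")
    eff = ct.efficiency[frame.index].to_numpy()[:, None]
    delta = frame.min(axis=1).to_numpy()[:, None] - frame.to_numpy()
    q = (1.0 + eff) ** delta
    return pd.DataFrame(q, index=frame.index, columns=frame.columns)


def pairwise_variation(q: pd.DataFrame, ranking: StabilityRanking,
                       ddof: int = 1) -> pd.Series:
    """geNorm V(n/n+1): pairwise variation of normalization factors.

    For the n and n+1 most stable genes (by reverse exclusion order), V is
    the SD over samples of log2(NF_n / NF_{n+1}), where NF_n is the geometric
    mean quantity of the n most stable genes. Used to decide how many
    reference genes suffice (conventional cutoff 0.15).
    """
    order = list(ranking.final_pair) + list(reversed(ranking.exclusion_order))
    q = _validate_quantities(q.loc[order])
    logq = np.log2(q.to_numpy())
    out = {}
    for n in range(2, len(order)):
        nf_n = logq[:n].mean(axis=0)
        nf_n1 = logq[: n + 1].mean(axis=0)
        out[f"V{n}/{n + 1}"] = float(np.std(nf_n - nf_n1, ddof=ddof))
    return pd.Series(out)


class GeNormRanker(BaseEstimator):
    """Estimator interface to geNorm stepwise stability ranking.

    ``fit(X)`` takes samples x genes strictly positive quantities (DataFrame
    column names become gene ids). Fitted attributes: ``ranking_`` (full
    trace), ``final_pair_``, ``m_values_`` (first-round M per gene) and
    ``exclusion_order_``.

    Parameters
    ----------
    ddof : int, default 1
        Delta degrees of freedom of the pairwise SD (1 = sample SD).
    """

    def __init__(self, ddof: int = 1):
        self.ddof = ddof

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            q = X.T.copy()
        else:
            X = np.asarray(X, dtype=float)
            q = pd.DataFrame(X.T, index=[f"g{i}" for i in range(X.shape[1])])
        self.n_features_in_ = q.shape[0]
        self.ranking_ = stepwise_ranking(q, ddof=self.ddof)
        self.final_pair_ = self.ranking_.final_pair
        self.m_values_ = pd.Series(self.ranking_.rounds[0].m_values)
        self.exclusion_order_ = list(self.ranking_.exclusion_order)
        return self

    def score(self, X=None, y=None):
        """Negative M of the final pair (higher = more stable)."""
        check_is_fitted(self, "ranking_")
        last = self.ranking_.rounds[-1]
        return -float(np.mean(list(last.m_values.values())))
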