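"""Synthetic RNA-Seq count matrices and qPCR Ct tables with planted structure.

The generator emulates the study design the pipeline targets: a bulk RNA-Seq
experiment over 47 samples spanning 14 genotypes and 4 phenological /
treatment conditions, with gene-level read counts whose means fall roughly in
the 330-3,700 reads/sample range. Three gene classes are planted:

``stable``
    negative-binomial counts with low dispersion and no condition effect —
    the housekeeping genes the pipeline should recover;
``de``
    low dispersion but a log2 fold-change in one randomly chosen condition —
    genes the NDE filter should reject;
``noisy``
    no condition effect but high biological dispersion — genes the CV
    threshold should reject.

Counts are NB with variance mu + phi * mu**2 (dispersion phi); phi = 0 is the
Poisson limit. Per-sample library-size factors are lognormal, renormalised to
geometric mean 1 so planted base means stay interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix, CtTable, ValidationError, child_seed


@dataclass
class SimConfig:
    """Shape and noise parameters of a simulated experiment.

    Defaults reproduce the target study's scale: 47 samples, 14 genotypes,
    4 conditions, base means 330-3,700 reads.
    """

    n_samples: int = 47
    n_conditions: int = 4
    n_genotypes: int = 14
    n_stable: int = 20
    n_de: int = 30
    n_noisy: int = 150
    mean_range: tuple[float, float] = (330.0, 3700.0)
    dispersion_stable: float = 0.05
    dispersion_noisy: float = 0.6
    de_log2fc: float = 2.0
    libsize_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stable < 0 or self.n_de < 0 or self.n_noisy < 0:
            raise ValidationError("gene class counts must be >= 0")
        if self.n_stable + self.n_de + self.n_noisy == 0:
            raise ValidationError("at least one gene must be requested")
        if not self.mean_range[0] < self.mean_range[1]:
            raise ValidationError("mean_range must be (low, high) with low < high")
        if self.dispersion_stable < 0 or self.dispersion_noisy < 0:
            raise ValidationError("dispersions must be >= 0")
        if self.n_samples < 2 or self.n_conditions < 1 or self.n_genotypes < 1:
            raise ValidationError("need >= 2 samples and >= 1 condition/genotype")

    @property
    def n_genes(self) -> int:
        return self.n_stable + self.n_de + self.n_noisy


@dataclass
class TruthLabels:
    """Ground truth for a simulated matrix: per-gene class, base mean and
    per-condition fold-changes (genes x conditions)."""

    labels: pd.Series
    base_mean: pd.Series
    fold_changes: pd.DataFrame

    def genes_of(self, cls: str) -> list[str]:
        return list(self.labels.index[self.labels == cls])


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """NB(mu, var = mu + phi mu^2); phi = 0 falls back to Poisson."""
    if phi == 0:
        return rng.poisson(mu)
    size = 1.0 / phi  # NB shape parameter
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def generate_count_matrix(cfg: SimConfig) -> tuple[CountMatrix, TruthLabels]:
    """Simulate a count matrix with planted stable / DE / noisy genes.

    Returns the matrix together with :class:`TruthLabels` for recovery tests.
    Reproducible: the same config (including seed) yields identical output.
    """
    rng = np.random.default_rng(child_seed(cfg.seed, "generate_count_matrix"))
    n_genes = cfg.n_genes

    conditions = [f"cond{i + 1}" for i in range(cfg.n_conditions)]
    # the last condition is the treated variant of the one before it,
    # mirroring a GA3-on-berries design; the others are untreated stages
    if cfg.n_conditions >= 2:
        stages = [f"stage{i + 1}" for i in range(cfg.n_conditions - 1)]
        stage_of = stages + [stages[-1]]
        treat_of = ["none"] * (cfg.n_conditions - 1) + ["GA3"]
    else:
        stage_of, treat_of = ["stage1"], ["none"]
    sample_ids = [f"S{i + 1:02d}" for i in range(cfg.n_samples)]
    cond_idx = [i % cfg.n_conditions for i in range(cfg.n_samples)]
    design = pd.DataFrame(
        {
            "genotype": [f"G{(i % cfg.n_genotypes) + 1:02d}" for i in range(cfg.n_samples)],
            "stage": [stage_of[c] for c in cond_idx],
            "treatment": [treat_of[c] for c in cond_idx],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    condition_of_sample = np.array([conditions[c] for c in cond_idx])

    gene_ids = [f"gene{i + 1:04d}" for i in range(n_genes)]
    classes = (
        ["stable"] * cfg.n_stable + ["de"] * cfg.n_de + ["noisy"] * cfg.n_noisy
    )
    labels = pd.Series(classes, index=pd.Index(gene_ids, name="gene_id"), name="label")

    low, high = cfg.mean_range
    base_mean = pd.Series(
        np.exp(rng.uniform(np.log(low), np.log(high), size=n_genes)),
        index=labels.index,
        name="base_mean",
    )

    fold = pd.DataFrame(1.0, index=labels.index, columns=conditions)
    de_ids = labels.index[labels == "de"]
    up_conditions = rng.integers(0, cfg.n_conditions, size=len(de_ids))
    signs = rng.choice([-1.0, 1.0], size=len(de_ids))
    for gid, ci, sgn in zip(de_ids, up_conditions, signs):
        fold.loc[gid, conditions[ci]] = 2.0 ** (sgn * cfg.de_log2fc)

    if cfg.libsize_sd > 0:
        log_sf = rng.normal(0.0, cfg.libsize_sd, size=cfg.n_samples)
        log_sf -= log_sf.mean()  # geometric mean 1
        size_factors = np.exp(log_sf)
    else:
        size_factors = np.ones(cfg.n_samples)

    fc_per_sample = fold.loc[:, condition_of_sample].to_numpy()  # genes x samples
    mu = base_mean.to_numpy()[:, None] * fc_per_sample * size_factors[None, :]

    counts = np.empty((n_genes, cfg.n_samples), dtype=np.int64)
    phi_of = {"stable": cfg.dispersion_stable, "de": cfg.dispersion_stable,
              "noisy": cfg.dispersion_noisy}
    for cls in ("stable", "de", "noisy"):
        mask = (labels == cls).to_numpy()
        if mask.any():
            counts[mask] = _nb_draw(rng, mu[mask], phi_of[cls])

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=labels.index, columns=sample_ids),
        design=design,
    )
    truth = TruthLabels(labels=labels, base_mean=base_mean, fold_changes=fold)
    return cm, truth


def generate_ct_table(
    expr: pd.DataFrame,
    efficiency: pd.Series | float,
    ct_noise_sd: float = 0.0,
    seed: int = 0,
    ct_ref: float = 34.0,
) -> CtTable:
    """Turn true relative quantities into simulated Ct values.

    Inverts the standard-curve transform: ``Ct = ct_ref - log(q)/log(1+E)``
    plus Gaussian measurement noise, so a quantity of 1 amplifies at
    ``ct_ref`` cycles and, at E = 1, doubling the quantity lowers Ct by
    exactly one cycle.

    Parameters
    ----------
    expr
        genes x samples strictly positive true quantities.
    efficiency
        per-gene amplification efficiency in (0, 2], scalar broadcast allowed.
    ct_noise_sd
        standard deviation of additive Gaussian Ct noise (cycles).
    """
    if (expr.to_numpy() <= 0).any():
        raise ValidationError("quantities must be strictly positive")
    if ct_noise_sd < 0:
        raise ValidationError("ct_noise_sd must be >= 0")
    if np.isscalar(efficiency):
        efficiency = pd.Series(float(efficiency), index=expr.index)
    elif not isinstance(efficiency, pd.Series):
        efficiency = pd.Series(np.asarray(efficiency, dtype=float), index=expr.index)
    eff = efficiency.reindex(expr.index).astype(float)
    if eff.isna().any() or ((eff <= 0) | (eff > 2)).any():
        raise ValidationError("efficiencies must lie in (0, 2] for every gene")

    rng = np.random.default_rng(child_seed(seed, "generate_ct_table"))
    ct = ct_ref - np.log(expr.to_numpy()) / np.log1p(eff.to_numpy())[:, None]
    if ct_noise_sd > 0:
        ct = ct + rng.normal(0.0, ct_noise_sd, size=ct.shape)
    return CtTable(ct=pd.DataFrame(ct, index=expr.index, columns=expr.columns),
                   efficiency=eff)
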