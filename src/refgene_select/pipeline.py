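"""End-to-end orchestration: counts -> NDE filter -> stats -> thresholds -> geNorm.

Mirrors the candidate-funnel of the underlying study: all genes -> the
non-differentially-expressed subset -> the high-mean / low-CV candidates ->
the final most-stable pair, with every stage written to plain files and a
machine-readable run manifest recording seeds, counts and content hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genorm import StabilityRanking, ct_preprocess, stepwise_ranking
from .io import (CountMatrix, CtTable, RunConfig, ValidationError, write_count_matrix,
                 write_report)
from .nde import select_nde
from .simulate import SimConfig, generate_count_matrix
from .stats import describe, gene_stats, rank_by_cv, stat_correlations
from .thresholds import sweep_table, threshold_sweep

logger = logging.getLogger("refgene_select")


@dataclass
class RunManifest:
    """Machine-readable record of one pipeline run."""

    config: dict
    seed: int
    version: str
    stage_counts: dict[str, int]
    file_hashes: dict[str, str] = field(default_factory=dict)
    final_pair: tuple[str, str] | None = None

    def validate_funnel(self) -> None:
        order = ["input_genes", "nde_genes", "selected_candidates"]
        vals = [self.stage_counts[k] for k in order if k in self.stage_counts]
        if any(a < b for a, b in zip(vals, vals[1:])):
            raise ValidationError(f"funnel must be non-increasing: {self.stage_counts}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    cfg: RunConfig,
    outdir: str | Path,
    counts: CountMatrix | None = None,
    sim_cfg: SimConfig | None = None,
    ct: CtTable | None = None,
) -> RunManifest:
    """Run every stage and write reports plus a manifest under ``outdir``.

    Provide either a real ``counts`` matrix or a ``sim_cfg`` to simulate one.
    If a Ct table is given (or simulation is requested), the geNorm stage
    runs on the selected candidates. Any stage validation error aborts with
    a stage-named message.
    """
    if (counts is None) == (sim_cfg is None):
        raise ValidationError("provide exactly one of counts or sim_cfg")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(obj, name: str) -> Path:
        path = outdir / name
        if isinstance(obj, CountMatrix):
            write_count_matrix(obj, path, outdir / "design.tsv")
            written.append(outdir / "design.tsv")
        else:
            write_report(obj, path)
        written.append(path)
        return path

    truth = None
    if sim_cfg is not None:
        stage = "simulate"
        counts, truth = generate_count_matrix(sim_cfg)
        _write(counts, "counts.tsv")
        _write(truth.labels.to_frame(), "truth_labels.csv")
    assert counts is not None

    try:
        stage = "nde_filter"
        nde_genes = select_nde(counts, cfg)
        nde_counts = CountMatrix(counts=counts.counts.loc[sorted(nde_genes)],
                                 design=counts.design) if nde_genes else None
        _write({"nde_genes": sorted(nde_genes)}, "nde_genes.json")

        stage = "selection_stats"
        if nde_counts is None:
            raise ValidationError("no genes survived the NDE filter")
        stats = gene_stats(nde_counts)
        _write(rank_by_cv(stats), "gene_stats.csv")
        _write(describe(stats), "stats_summary.csv")
        if len(stats) >= 3:
            _write(stat_correlations(stats), "stat_correlations.csv")

        stage = "resampling_thresholds"
        sweep = threshold_sweep(nde_counts, stats, cfg)
        _write(sweep_table(sweep), "threshold_sweep.csv")
        primary = _primary_result(sweep)
        _write(primary, "selected_candidates.json")

        final_pair = None
        if ct is not None or truth is not None:
            stage = "genorm_stability"
            if ct is None:
                # derive a Ct table for the selected candidates from simulated
                # expression (library-size-normalised counts as quantities)
                from .simulate import generate_ct_table
                from .nde import size_factors

                candidates = primary.selected or sorted(nde_genes)
                if len(candidates) >= 3:
                    sf = size_factors(counts)
                    expr = counts.counts.loc[candidates].astype(float).div(sf, axis=1)
                    expr = expr.clip(lower=0.5)  # guard zero counts
                    expr = expr.div(expr.max(axis=1), axis=0)
                    ct = generate_ct_table(expr, efficiency=1.0, ct_noise_sd=0.0,
                                           seed=cfg.seed)
            if ct is not None and ct.ct.shape[0] >= 3:
                q = ct_preprocess(ct)
                ranking = stepwise_ranking(q)
                _write(_ranking_report(ranking), "genorm_ranking.json")
                _write(ranking.m_trace(), "genorm_m_trace.csv")
                final_pair = ranking.final_pair
    except ValidationError as exc:
        raise ValidationError(f"[{stage}] {exc}") from exc

    manifest = RunManifest(
        config=dataclasses.asdict(cfg),
        seed=cfg.seed,
        version=__version__,
        stage_counts={
            "input_genes": counts.n_genes,
            "nde_genes": len(nde_genes),
            "selected_candidates": primary.n_selected,
        },
        final_pair=final_pair,
    )
    manifest.validate_funnel()
    for path in written:
        manifest.file_hashes[path.name] = _sha256(path)
    write_report(manifest, outdir / "manifest.json")
    logger.info("pipeline complete: %s", manifest.stage_counts)
    return manifest


def _primary_result(sweep):
    """The sweep row used for the candidate set: prefer (2.5%, 97.5%)."""
    for res in sweep:
        if (res.cv_percentile, res.mu_percentile) == (0.025, 0.975):
            return res
    return sweep[0]


def _ranking_report(ranking: StabilityRanking) -> dict:
    return {
        "final_pair": list(ranking.final_pair),
        "exclusion_order": ranking.exclusion_order,
        "rounds": [
            {"remaining": r.remaining, "m_values": r.m_values, "excluded": r.excluded}
            for r in ranking.rounds
        ],
    }
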