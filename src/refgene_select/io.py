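"""Tabular I/O, run configuration, and seeded randomness shared by the pipeline.

File conventions
----------------
Count matrix : TSV/CSV, UTF-8, header row of sample ids, first column gene id,
    genes in rows. Counts are non-negative integers.
Design table : TSV with columns ``sample_id, genotype, stage, treatment``.
Ct table     : TSV, genes x samples, missing values as empty cells, plus an
    ``efficiency`` column (per-gene amplification efficiency in (0, 2]).
Reports      : CSV for per-gene tables, JSON for nested results. Decimal
    separator is always "." regardless of locale.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("refgene_select")

DESIGN_COLUMNS = ("genotype", "stage", "treatment")

#: percentile pairs (cv_percentile, mu_percentile) used by the threshold sweep
DEFAULT_PERCENTILE_PAIRS: tuple[tuple[float, float], ...] = (
    (0.05, 0.95),
    (0.025, 0.975),
    (0.01, 0.99),
    (0.001, 0.999),
)


class ValidationError(ValueError):
    """Raised when an input violates a pipeline invariant."""


@dataclass
class CountMatrix:
    """A genes x samples matrix of read counts with per-sample design labels.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, index = gene ids, columns =
        sample ids.
    design
        DataFrame indexed by sample id with columns ``genotype``, ``stage``
        and ``treatment``. Every sample in ``counts`` must appear here.
    """

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.shape[0] < 1 or counts.shape[1] < 2:
            raise ValidationError(
                f"count matrix needs >= 1 gene and >= 2 samples, got {counts.shape}"
            )
        if counts.index.duplicated().any():
            dupes = counts.index[counts.index.duplicated()].tolist()
            raise ValidationError(f"duplicate gene ids: {dupes}")
        if counts.columns.duplicated().any():
            dupes = counts.columns[counts.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values), atol=0):
                raise ValidationError("counts must be integers")
            counts = counts.astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        missing = set(counts.columns) - set(self.design.index)
        if missing:
            raise ValidationError(f"samples absent from design: {sorted(missing)}")
        for col in DESIGN_COLUMNS:
            if col not in self.design.columns:
                raise ValidationError(f"design table lacks column {col!r}")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "design", self.design.loc[list(counts.columns)])

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def condition_labels(self) -> pd.Series:
        """Per-sample condition label: the (stage, treatment) combination.

        The experimental conditions compared by the DE filter are the
        distinct phenological-stage / treatment combinations.
        """
        d = self.design
        return (d["stage"].astype(str) + "|" + d["treatment"].astype(str)).rename(
            "condition"
        )


@dataclass
class CtTable:
    """qPCR threshold-cycle values per gene x sample with per-gene efficiency.

    Missing Ct values are NaN. ``efficiency`` is the per-gene amplification
    efficiency E in (0, 2] (1.0 = perfect doubling per cycle).
    """

    ct: pd.DataFrame
    efficiency: pd.Series

    def __post_init__(self) -> None:
        if self.ct.index.duplicated().any():
            raise ValidationError("duplicate gene ids in Ct table")
        eff = self.efficiency.reindex(self.ct.index)
        if eff.isna().any():
            missing = eff.index[eff.isna()].tolist()
            raise ValidationError(f"genes without efficiency: {missing}")
        if ((eff <= 0) | (eff > 2)).any():
            raise ValidationError("efficiencies must lie in (0, 2]")
        object.__setattr__(self, "efficiency", eff.astype(float))
        object.__setattr__(self, "ct", self.ct.astype(float))


@dataclass
class RunConfig:
    """Configuration for a full selection run."""

    n_pseudo: int = 10_000
    percentile_pairs: tuple[tuple[float, float], ...] = DEFAULT_PERCENTILE_PAIRS
    min_reads_per_sample: int = 100
    alpha: float = 0.05
    max_cv: float | None = None  # optional variation-index cap (disabled)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pseudo < 1:
            raise ValidationError("n_pseudo must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.min_reads_per_sample < 0:
            raise ValidationError("min_reads_per_sample must be >= 0")
        pairs = tuple(tuple(p) for p in self.percentile_pairs)
        for cv_p, mu_p in pairs:
            if not (0 < cv_p < mu_p < 1):
                raise ValidationError(
                    f"need 0 < cv_percentile < mu_percentile < 1, got ({cv_p}, {mu_p})"
                )
        object.__setattr__(self, "percentile_pairs", pairs)


def child_seed(seed: int, label: str) -> int:
    """Deterministic per-operation child seed derived from the run seed.

    Hashing keeps independent stages decoupled: adding a draw to one stage
    never shifts the stream of another. Result is < 2**31.
    """
    digest = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def read_count_matrix(path: str | Path, design_path: str | Path) -> CountMatrix:
    """Read a delimited count matrix plus its design table.

    Raises a parse error naming the offending row/column for malformed
    numbers; duplicate ids and unknown samples raise :class:`ValidationError`.
    """
    path, design_path = Path(path), Path(design_path)
    raw = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    counts = pd.DataFrame(index=raw.index.astype(str), columns=raw.columns.astype(str))
    parsed = {}
    for col in raw.columns:
        try:
            parsed[col] = pd.to_numeric(raw[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = raw[raw[col].apply(_not_numeric)].index
            row = bad[0] if len(bad) else "?"
            raise ValidationError(
                f"malformed count at gene {row!r}, sample {col!r} in {path}"
            ) from exc
    counts = pd.DataFrame(parsed, index=raw.index.astype(str))
    design = pd.read_csv(design_path, sep=_sep_for(design_path), dtype=str)
    if "sample_id" not in design.columns:
        raise ValidationError("design table must have a sample_id column")
    design = design.set_index("sample_id")
    return CountMatrix(counts=counts, design=design)


def _not_numeric(x: object) -> bool:
    try:
        float(x)  # type: ignore[arg-type]
        return False
    except (TypeError, ValueError):
        return True


def write_count_matrix(cm: CountMatrix, path: str | Path, design_path: str | Path | None = None) -> None:
    path = Path(path)
    out = cm.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep=_sep_for(path))
    if design_path is not None:
        design_path = Path(design_path)
        d = cm.design.copy()
        d.index.name = "sample_id"
        d.to_csv(design_path, sep=_sep_for(design_path))


def read_ct_table(path: str | Path) -> CtTable:
    """Read a Ct TSV (genes x samples, ``efficiency`` column, blanks = missing)."""
    path = Path(path)
    raw = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if "efficiency" not in raw.columns:
        raise ValidationError("Ct table must carry an 'efficiency' column")
    eff = raw["efficiency"].astype(float)
    ct = raw.drop(columns=["efficiency"]).astype(float)
    return CtTable(ct=ct, efficiency=eff)


def write_ct_table(table: CtTable, path: str | Path) -> None:
    path = Path(path)
    out = table.ct.copy()
    out.insert(0, "efficiency", table.efficiency)
    out.index.name = "gene_id"
    out.to_csv(path, sep=_sep_for(path))


def read_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML key-value file."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    if "percentile_pairs" in data:
        data["percentile_pairs"] = tuple(tuple(p) for p in data["percentile_pairs"])
    return RunConfig(**data)


def write_report(results: object, path: str | Path) -> None:
    """Write a pipeline result: CSV for tabular, JSON for nested results.

    DataFrames go to CSV with full float precision (round-trips to 12+
    significant digits); dataclasses and dicts go to JSON with deterministic
    key order.
    """
    path = Path(path)
    if isinstance(results, pd.DataFrame):
        results.to_csv(path, index=not isinstance(results.index, pd.RangeIndex),
                       float_format="%.15g")
        return
    if dataclasses.is_dataclass(results) and not isinstance(results, type):
        payload = _jsonable(results)
    elif isinstance(results, (dict, list)):
        payload = _jsonable(results)
    else:
        raise ValidationError(f"unsupported report type: {type(results).__name__}")
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=False)
        fh.write("\n")


def _jsonable(obj: object) -> object:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        seq = sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
        return [_jsonable(v) for v in seq]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, pd.Series):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="split"))
    return obj
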