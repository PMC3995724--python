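"""Expression preprocessing and miRNA selection.

Genes with any missing value are removed outright (correlations over
subsets must never silently change their sample basis).  Normalization is
quantile by default, applied separately to the miRNA and mRNA matrices;
``median_center`` and ``none`` are available for pre-normalized inputs.

An miRNA is analyzable when it has at least ``min_targets`` catalogued
targets present in the mRNA matrix and is detected (log2 intensity strictly
above ``expression_cutoff``, default 7.25) in at least
``min_expressed_tissues`` samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .data_io import ExpressionMatrix, MTICatalog

__all__ = [
    "PreprocessConfig",
    "drop_incomplete_genes",
    "normalize",
    "quantile_normalize",
    "expressed_tissues",
    "select_mirnas",
    "MirnaSelection",
    "load_config",
    "DEFAULT_EXPRESSION_CUTOFF",
]

#: Detection cutoff on the log2 scale used for miRNA expression screening.
DEFAULT_EXPRESSION_CUTOFF = 7.25

_NORMALIZATION_METHODS = ("quantile", "median_center", "none")


@dataclass(frozen=True)
class PreprocessConfig:
    expression_cutoff: float = DEFAULT_EXPRESSION_CUTOFF
    min_targets: int = 10
    min_expressed_tissues: int = 30
    normalization: str = "quantile"

    def __post_init__(self) -> None:
        if not np.isfinite(self.expression_cutoff):
            raise ValueError("expression_cutoff must be finite")
        if self.min_targets < 1:
            raise ValueError(f"min_targets must be >= 1, got {self.min_targets}")
        if self.min_expressed_tissues < 3:
            raise ValueError(f"min_expressed_tissues must be >= 3, got {self.min_expressed_tissues}")
        if self.normalization not in _NORMALIZATION_METHODS:
            raise ValueError(
                f"unknown normalization {self.normalization!r}; choose from {_NORMALIZATION_METHODS}"
            )


def load_config(path: str | Path) -> PreprocessConfig:
    """Read a YAML or JSON config with the PreprocessConfig keys."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must hold a mapping")
    return PreprocessConfig(**data)


def drop_incomplete_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Retain exactly the features with no missing value in any sample."""
    complete = ~np.isnan(matrix.values).any(axis=1)
    if not complete.any():
        raise ValueError("every feature has at least one missing value; nothing left after filtering")
    if complete.all():
        return matrix
    kept = [f for f, ok in zip(matrix.feature_ids, complete) if ok]
    return ExpressionMatrix(kept, matrix.samples, matrix.values[complete])


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Classic quantile normalization across columns.

    Every column is remapped onto the mean of the column-wise sorted values,
    so all columns share the identical value multiset afterwards.  Ties
    within a column are resolved by original order (stable sort), which
    preserves within-column ranks.
    """
    order = np.argsort(values, axis=0, kind="stable")
    ranks = np.empty_like(order)
    n_rows, n_cols = values.shape
    row_idx = np.arange(n_rows)[:, None]
    ranks[order, np.arange(n_cols)[None, :]] = row_idx
    reference = np.sort(values, axis=0).mean(axis=1)
    return reference[ranks]


def normalize(matrix: ExpressionMatrix, method: str) -> ExpressionMatrix:
    """Normalize sample columns; requires a complete matrix.

    ``quantile``: all columns share one sorted value multiset.
    ``median_center``: every column's median becomes 0.
    ``none``: identity (returns the input object).
    """
    if method not in _NORMALIZATION_METHODS:
        raise ValueError(f"unknown normalization {method!r}; choose from {_NORMALIZATION_METHODS}")
    if method == "none":
        return matrix
    if np.isnan(matrix.values).any():
        raise ValueError("normalize requires a complete matrix; run drop_incomplete_genes first")
    if method == "quantile":
        values = quantile_normalize(matrix.values)
    else:
        values = matrix.values - np.median(matrix.values, axis=0, keepdims=True)
    return ExpressionMatrix(matrix.feature_ids, matrix.samples, values)


def expressed_tissues(matrix: ExpressionMatrix, feature_id: str, cutoff: float) -> list[str]:
    """Samples where the feature exceeds the cutoff strictly, in matrix order."""
    row = matrix.row(feature_id)
    return [s for s, v in zip(matrix.sample_ids, row) if v > cutoff]


@dataclass(frozen=True)
class MirnaSelection:
    """Outcome of miRNA screening, with per-candidate diagnostics.

    ``diagnostics`` maps each catalog miRNA present in the matrix to
    ``(n_targets, n_expressed, reason)`` where ``reason`` is ``"selected"``
    or the exclusion cause.
    """

    selected: tuple[str, ...]
    diagnostics: dict[str, tuple[int, int, str]]


def select_mirnas(
    mirna_matrix: ExpressionMatrix,
    catalog: MTICatalog,
    config: PreprocessConfig,
) -> MirnaSelection:
    """Screen catalog miRNAs for analyzability.

    Keeps miRNAs with N_m >= ``min_targets`` targets present in the catalog
    and at least ``min_expressed_tissues`` samples above the expression
    cutoff.  Order follows descending N_m, then miRNA id (stable across
    catalog row order).  Raises if nothing passes, listing near-misses.
    """
    diagnostics: dict[str, tuple[int, int, str]] = {}
    candidates = sorted(catalog.mirnas, key=lambda m: (-catalog.n_targets(m), m))
    selected: list[str] = []
    for mirna in candidates:
        if mirna not in mirna_matrix:
            diagnostics[mirna] = (catalog.n_targets(mirna), 0, "not profiled in miRNA matrix")
            continue
        n_targets = catalog.n_targets(mirna)
        n_expressed = len(expressed_tissues(mirna_matrix, mirna, config.expression_cutoff))
        if n_targets < config.min_targets:
            reason = f"insufficient targets ({n_targets} < {config.min_targets})"
        elif n_expressed < config.min_expressed_tissues:
            reason = f"insufficient expressed tissues ({n_expressed} < {config.min_expressed_tissues})"
        else:
            reason = "selected"
            selected.append(mirna)
        diagnostics[mirna] = (n_targets, n_expressed, reason)
    if not selected:
        near = sorted(diagnostics.items(), key=lambda kv: (-kv[1][0], -kv[1][1]))[:10]
        raise ValueError(f"no miRNA passed selection; closest candidates: {near}")
    return MirnaSelection(selected=tuple(selected), diagnostics=diagnostics)
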