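"""Selection-quality diagnostics.

Three views on how much a selected tissue subset improves miRNA--target
anti-correlation: the S - A improvement (mean correlation over the selected
tissues minus the mean over all tissues), a permutation test that compares
the selected subset's loss with losses of random same-size subsets from the
same candidate universe, and overlaid correlation-density curves.

The permutation p-value is a diagnostic, not an inference: when the subset
was itself chosen by minimizing the same loss over the same data, selection
and test share data and the p-value is optimistically biased.  Every report
carries that note.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_stats import (
    CandidateSubset,
    DENSITY_GRID,
    correlation_density,
    correlation_profile,
    loss,
)
from .data_io import ExpressionMatrix
from .preprocess import DEFAULT_EXPRESSION_CUTOFF
from .search import _evaluate_index_batch, _random_index_batches, candidate_tissues

__all__ = [
    "ImprovementRecord",
    "PermutationReport",
    "improvement",
    "permutation_test",
    "density_comparison",
    "plot_density_comparison",
]

_PERMUTATION_NOTE = (
    "diagnostic only: when the subset was selected by minimizing this same loss, "
    "selection and test share data and the p-value is optimistically biased"
)


@dataclass(frozen=True)
class ImprovementRecord:
    """S - A: selected-tissue mean correlation minus the all-tissue mean."""

    mirna_id: str
    all_tissue_mean: float   # A
    selected_mean: float     # S
    delta: float             # S - A


@dataclass(frozen=True)
class PermutationReport:
    mirna_id: str
    observed_loss: float
    null_losses: tuple[float, ...]
    empirical_p: float
    B: int
    note: str = _PERMUTATION_NOTE


def improvement(
    mirna_id: str,
    targets: Sequence[str],
    mirna_matrix: ExpressionMatrix,
    mrna_matrix: ExpressionMatrix,
    selected: CandidateSubset,
) -> ImprovementRecord:
    """Mean miRNA--target correlation over all tissues (A), over the
    selected tissues (S), and the improvement S - A."""
    all_subset = CandidateSubset(mirna_matrix.sample_ids)
    a_profile = correlation_profile(mirna_id, targets, mirna_matrix, mrna_matrix, all_subset)
    s_profile = correlation_profile(mirna_id, targets, mirna_matrix, mrna_matrix, selected)
    a_mean = a_profile.mean_corr
    s_mean = s_profile.mean_corr
    return ImprovementRecord(
        mirna_id=mirna_id,
        all_tissue_mean=a_mean,
        selected_mean=s_mean,
        delta=s_mean - a_mean,
    )


def permutation_test(
    mirna_id: str,
    targets: Sequence[str],
    mirna_matrix: ExpressionMatrix,
    mrna_matrix: ExpressionMatrix,
    selected: CandidateSubset,
    B: int = 1000,
    seed: int = 0,
    a: float = 0.4,
    candidates: Sequence[str] | None = None,
    cutoff: float = DEFAULT_EXPRESSION_CUTOFF,
) -> PermutationReport:
    """Compare the selected subset's loss with B random same-size subsets.

    Null subsets are drawn uniformly from the miRNA's candidate universe
    (tissues above the expression cutoff, or ``candidates`` if given).  The
    +1-corrected empirical p is ``(1 + #{null <= observed}) / (B + 1)`` and
    never exactly zero.
    """
    if B < 19:
        raise ValueError(f"B must be >= 19 for a meaningful permutation p, got {B}")
    if candidates is None:
        candidates = candidate_tissues(mirna_id, mirna_matrix, cutoff, k_min=2)
    candidates = list(candidates)
    if len(candidates) <= selected.n_A:
        raise ValueError(
            f"candidate universe ({len(candidates)}) must exceed the selected size ({selected.n_A}); "
            "no null subsets can be drawn"
        )
    observed_profile = correlation_profile(mirna_id, targets, mirna_matrix, mrna_matrix, selected)
    observed = loss(observed_profile, a)

    cols = mirna_matrix.sample_positions(candidates)
    m = mirna_matrix.row(mirna_id)[cols]
    t_cols = mrna_matrix.sample_positions(candidates)
    targets_matrix = mrna_matrix.rows(list(targets))[:, t_cols]
    rng = np.random.default_rng(seed)
    null_losses: list[float] = []
    for idx in _random_index_batches(len(candidates), selected.n_A, B, rng):
        null_losses.extend(_evaluate_index_batch(m, targets_matrix, idx, a).tolist())
    null = np.asarray(null_losses)
    p = (1 + int(np.sum(null <= observed))) / (B + 1)
    return PermutationReport(
        mirna_id=mirna_id,
        observed_loss=observed,
        null_losses=tuple(null.tolist()),
        empirical_p=p,
        B=B,
    )


def density_comparison(
    profiles: Sequence[tuple[str, Sequence[float]]],
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Aligned correlation-density curves for overlay plotting.

    Returns a table with the shared grid column ``x`` plus one density
    column per label, and a mapping label -> sample skewness.
    """
    if not profiles:
        raise ValueError("no correlation sets supplied")
    columns: dict[str, np.ndarray] = {"x": DENSITY_GRID.copy()}
    skewness: dict[str, float] = {}
    for label, values in profiles:
        curve = correlation_density(values)
        columns[str(label)] = curve.density
        skewness[str(label)] = curve.skewness
    return pd.DataFrame(columns), skewness


def plot_density_comparison(table: pd.DataFrame, path: str, title: str | None = None) -> None:
    """Write an overlay plot of density curves (PNG/SVG by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for column in table.columns:
        if column == "x":
            continue
        ax.plot(table["x"], table[column], label=column)
    ax.set_xlabel("Pearson correlation")
    ax.set_ylabel("density")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
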