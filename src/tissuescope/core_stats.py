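"""Correlation, negative-proportion and loss arithmetic.

For an miRNA *m* with N_m validated targets and a tissue subset A, the
selection criterion combines (i) the mean Pearson correlation r̄_A between
the miRNA and its targets across A and (ii) the proportion p_neg of those
correlations that are strictly negative:

    L_a(A) = a * r̄_A + (1 - a) * (1 - p_neg),        0 < a < 1

L is minimized when the targets are strongly anti-correlated with the miRNA
(r̄_A near -1) and nearly all correlations are negative (p_neg near 1); its
range is [-a, 1].  The weight ``a`` trades the two terms off; weights below
0.5 emphasize the negative-proportion term.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "UndefinedCorrelationError",
    "CandidateSubset",
    "CorrelationProfile",
    "LossConfig",
    "DensityCurve",
    "pearson_correlation",
    "correlation_profile",
    "loss",
    "loss_from_stats",
    "correlation_density",
    "DENSITY_GRID",
]

#: Fixed evaluation grid for correlation densities (reproducible exports).
DENSITY_GRID = np.linspace(-1.1, 1.1, 512)


class UndefinedCorrelationError(ValueError):
    """Pearson correlation is undefined (a constant vector, or n < 2)."""


@dataclass(frozen=True)
class CandidateSubset:
    """A set of tissue-sample ids — the unit the search optimizes over.

    Ids are stored sorted, so equal sets compare equal regardless of input
    order.  At least two samples are required for correlation to exist.
    """

    sample_ids: tuple[str, ...]

    def __init__(self, sample_ids: Sequence[str]):
        ids = tuple(sorted(sample_ids))
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in subset")
        if len(ids) < 2:
            raise ValueError(f"subset needs at least 2 samples, got {len(ids)}")
        object.__setattr__(self, "sample_ids", ids)

    @property
    def n_A(self) -> int:
        return len(self.sample_ids)

    def __iter__(self):
        return iter(self.sample_ids)

    def __len__(self) -> int:
        return len(self.sample_ids)


@dataclass(frozen=True)
class CorrelationProfile:
    """Per-target correlations of one miRNA over one tissue subset.

    ``correlations`` holds one Pearson coefficient per usable target, in
    catalog order; ``skipped_targets`` lists targets dropped because their
    correlation was undefined on this subset (constant vector).  ``p_neg``
    counts strictly negative coefficients over the usable targets.
    """

    mirna_id: str
    subset: CandidateSubset
    target_ids: tuple[str, ...]
    correlations: tuple[float, ...]
    skipped_targets: tuple[str, ...] = ()

    @property
    def n_targets(self) -> int:
        return len(self.correlations)

    @property
    def mean_corr(self) -> float:
        """r̄_A — arithmetic mean of the target correlations."""
        return float(np.mean(self.correlations))

    @property
    def n_neg(self) -> int:
        return int(np.sum(np.asarray(self.correlations) < 0.0))

    @property
    def p_neg(self) -> float:
        return self.n_neg / self.n_targets


@dataclass(frozen=True)
class LossConfig:
    """Search configuration: loss weight, sampling size and k range.

    ``a`` weights mean correlation against the positive-correlation
    proportion (below 0.5 emphasizes the latter).  ``M`` is the number of
    random subsets drawn per k; searches switch to exhaustive enumeration
    when C(n, k) <= M.
    """

    a: float = 0.4
    M: int = 100_000
    k_min: int = 3
    k_max: int = 15
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.a < 1.0:
            raise ValueError(f"loss weight a must lie strictly between 0 and 1, got {self.a}")
        if self.M < 1:
            raise ValueError(f"sample count M must be >= 1, got {self.M}")
        if not 2 <= self.k_min <= self.k_max:
            raise ValueError(f"need 2 <= k_min <= k_max, got k_min={self.k_min}, k_max={self.k_max}")


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation of two equal-length vectors.

    Raises :class:`UndefinedCorrelationError` if either vector is constant
    or fewer than two points are given.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"vectors must be 1-D and equal length, got shapes {x.shape} and {y.shape}")
    if x.size < 2:
        raise UndefinedCorrelationError(f"need at least 2 points, got {x.size}")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        raise UndefinedCorrelationError("constant vector: correlation undefined")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def correlation_profile(
    mirna_id: str,
    targets: Sequence[str],
    mirna_matrix,
    mrna_matrix,
    subset: CandidateSubset,
    undefined: str = "skip",
) -> CorrelationProfile:
    """Correlate one miRNA with each of its targets across a tissue subset.

    ``undefined`` controls constant-vector targets: ``"skip"`` drops them
    from the profile (shrinking the denominator of p_neg), ``"fail"``
    raises.  Raises if no usable target remains.
    """
    if undefined not in ("skip", "fail"):
        raise ValueError(f"undefined policy must be 'skip' or 'fail', got {undefined!r}")
    cols = mirna_matrix.sample_positions(subset.sample_ids)
    m = mirna_matrix.row(mirna_id)[cols]
    mrna_cols = mrna_matrix.sample_positions(subset.sample_ids)
    correlations: list[float] = []
    kept: list[str] = []
    skipped: list[str] = []
    for gene in targets:
        y = mrna_matrix.row(gene)[mrna_cols]
        try:
            r = pearson_correlation(m, y)
        except UndefinedCorrelationError:
            if undefined == "fail":
                raise UndefinedCorrelationError(
                    f"correlation of {mirna_id} with {gene} undefined on subset {subset.sample_ids}"
                ) from None
            skipped.append(gene)
            continue
        correlations.append(r)
        kept.append(gene)
    if not correlations:
        raise UndefinedCorrelationError(
            f"no usable target for {mirna_id} on subset {subset.sample_ids} (all correlations undefined)"
        )
    return CorrelationProfile(
        mirna_id=mirna_id,
        subset=subset,
        target_ids=tuple(kept),
        correlations=tuple(correlations),
        skipped_targets=tuple(skipped),
    )


def loss_from_stats(mean_corr: float, p_neg: float, a: float) -> float:
    """L_a = a * r̄ + (1 - a) * (1 - p_neg)."""
    if not 0.0 < a < 1.0:
        raise ValueError(f"loss weight a must lie strictly between 0 and 1, got {a}")
    return a * mean_corr + (1.0 - a) * (1.0 - p_neg)


def loss(profile: CorrelationProfile, a: float) -> float:
    """Loss of a correlation profile; lies in [-a, 1]."""
    return loss_from_stats(profile.mean_corr, profile.p_neg, a)


@dataclass(frozen=True)
class DensityCurve:
    """Gaussian-kernel density of a correlation set on the fixed grid."""

    x: np.ndarray
    density: np.ndarray
    skewness: float
    bandwidth: float

    def to_table(self) -> np.ndarray:
        return np.column_stack([self.x, self.density])


def correlation_density(correlations: Sequence[float], bandwidth: float | str = "silverman") -> DensityCurve:
    """KDE of a correlation sample over [-1.1, 1.1] plus its skewness.

    Silverman's rule by default; a positive float fixes the KDE factor.
    Sample skewness > 0 makes "right-skewed" an assertable statement.
    """
    values = np.asarray(correlations, dtype=float)
    if values.size < 3:
        raise ValueError(f"need at least 3 correlations for a density, got {values.size}")
    if np.ptp(values) == 0.0:
        raise ValueError("all correlations identical: density degenerate")
    if isinstance(bandwidth, str):
        if bandwidth != "silverman":
            raise ValueError(f"bandwidth must be 'silverman' or a positive float, got {bandwidth!r}")
        bw_method = "silverman"
    else:
        if bandwidth <= 0:
            raise ValueError(f"bandwidth must be positive, got {bandwidth}")
        bw_method = bandwidth
    kde = stats.gaussian_kde(values, bw_method=bw_method)
    density = kde(DENSITY_GRID)
    return DensityCurve(
        x=DENSITY_GRID.copy(),
        density=density,
        skewness=float(stats.skew(values)),
        bandwidth=float(kde.factor),
    )
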