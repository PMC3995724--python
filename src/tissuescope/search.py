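"""The correlation loss function algorithm.

For one miRNA, the candidate universe is the set of tissues where its log2
expression exceeds the detection cutoff.  For each subset size k, the search
draws M k-subsets of that universe (or enumerates all of them when
C(n, k) <= M), scores each with the loss
``L_a = a * mean_corr + (1 - a) * (1 - p_neg)`` over the miRNA's validated
targets, and keeps the minimizer.  Repeating over k = k_min..k_max yields a
per-k profile and a global best; tissues are then ranked by how often they
occur across the per-k best sets, and a selected subset can be extended to
all samples sharing an (organ, tumor/normal) class with it.

Ties are broken deterministically: among equal-loss subsets the
lexicographically smallest sorted sample-id tuple wins; across k, the
smaller k wins first, then the id tuple.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .core_stats import (
    CandidateSubset,
    CorrelationProfile,
    LossConfig,
    UndefinedCorrelationError,
    correlation_profile,
    loss,
)
from .data_io import ExpressionMatrix, SampleAnnotation
from .preprocess import DEFAULT_EXPRESSION_CUTOFF

__all__ = [
    "SubsetSearchResult",
    "TissueRanking",
    "RankEntry",
    "candidate_tissues",
    "sample_subsets",
    "search_best_subset",
    "search_over_k",
    "rank_tissues",
    "extend_to_organs",
]

_MODES = ("auto", "random", "exhaustive", "seeded")
_BATCH = 16384


@dataclass(frozen=True)
class SubsetSearchResult:
    """Best subset found for one (miRNA, k) pair.

    ``best_loss`` is recomputed from ``profile`` via the scalar loss path,
    so it is exactly reproducible from ``best_subset``.  ``mode`` records
    how subsets were generated ("exhaustive" implies
    ``n_evaluated == C(n_candidates, k)``).
    """

    mirna_id: str
    k: int
    best_subset: CandidateSubset
    best_loss: float
    profile: CorrelationProfile
    n_evaluated: int
    mode: str


@dataclass(frozen=True)
class RankEntry:
    sample_id: str
    occurrence_count: int
    rank: int


@dataclass(frozen=True)
class TissueRanking:
    """Tissues ordered by occurrence across the per-k best sets."""

    entries: tuple[RankEntry, ...]
    source_k_values: tuple[int, ...]


def candidate_tissues(
    mirna_id: str,
    mirna_matrix: ExpressionMatrix,
    cutoff: float = DEFAULT_EXPRESSION_CUTOFF,
    k_min: int = 2,
) -> list[str]:
    """Universe of tissues where the miRNA exceeds the cutoff strictly."""
    row = mirna_matrix.row(mirna_id)
    ids = [s for s, v in zip(mirna_matrix.sample_ids, row) if v > cutoff]
    if len(ids) < k_min:
        raise ValueError(
            f"{mirna_id}: only {len(ids)} tissues above cutoff {cutoff}, need at least {k_min}"
        )
    return ids


# -- subset generation -----------------------------------------------------


def _random_index_batches(n: int, k: int, M: int, rng: np.random.Generator) -> Iterator[np.ndarray]:
    """Uniform k-subset index batches, a deterministic prefix-stable stream.

    Each subset is the k smallest positions of a row of i.i.d. uniform keys,
    which is uniform over k-combinations.  Because the generator is consumed
    row by row, the first M1 subsets of a run with M2 > M1 are identical to
    the M1-subset run (nested sampling streams).
    """
    remaining = M
    while remaining > 0:
        b = min(_BATCH, remaining)
        keys = rng.random((b, n))
        if k >= n:
            idx = np.tile(np.arange(n, dtype=np.intp), (b, 1))
        else:
            idx = np.argpartition(keys, k - 1, axis=1)[:, :k].astype(np.intp)
        yield idx
        remaining -= b


def _exhaustive_index_batches(n: int, k: int) -> Iterator[np.ndarray]:
    combos = itertools.combinations(range(n), k)
    while True:
        chunk = list(itertools.islice(combos, _BATCH))
        if not chunk:
            return
        yield np.array(chunk, dtype=np.intp)


def _seeded_index_batches(
    n: int, k: int, M: int, rng: np.random.Generator, seed_positions: np.ndarray
) -> Iterator[np.ndarray]:
    """Every subset contains all seed positions; remainder drawn uniformly."""
    free = np.setdiff1d(np.arange(n, dtype=np.intp), seed_positions)
    extra = k - seed_positions.size
    if extra == 0:
        yield np.tile(np.sort(seed_positions), (1, 1))
        return
    for idx in _random_index_batches(free.size, extra, M, rng):
        yield np.concatenate([np.tile(seed_positions, (idx.shape[0], 1)), free[idx]], axis=1)


def _index_batches(
    n: int,
    k: int,
    M: int,
    mode: str,
    rng: np.random.Generator | None,
    seed_positions: np.ndarray | None,
) -> tuple[str, Iterator[np.ndarray]]:
    """Resolve mode (incl. auto-switch) and return (effective_mode, batches)."""
    if mode not in _MODES:
        raise ValueError(f"unknown mode {mode!r}; choose from {_MODES}")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} candidate tissues")
    if mode == "auto":
        mode = "exhaustive" if math.comb(n, k) <= M else "random"
    if mode == "exhaustive":
        return mode, _exhaustive_index_batches(n, k)
    if M < 1:
        raise ValueError(f"M must be >= 1, got {M}")
    assert rng is not None
    if mode == "seeded":
        if seed_positions is None:
            raise ValueError("seeded mode requires seed_tissues")
        return mode, _seeded_index_batches(n, k, M, rng, seed_positions)
    return "random", _random_index_batches(n, k, M, rng)


def sample_subsets(
    candidates: Sequence[str],
    k: int,
    M: int,
    seed: int,
    mode: str = "auto",
    seed_tissues: Sequence[str] | None = None,
) -> Iterator[CandidateSubset]:
    """Stream candidate subsets of size k.

    ``random``: M independent uniform draws (duplicates across draws
    permitted).  ``exhaustive``: every k-combination exactly once.
    ``seeded``: every subset contains all ``seed_tissues``.  ``auto`` picks
    exhaustive when C(n, k) <= M, else random.  Identical arguments yield an
    identical stream.
    """
    candidates = list(candidates)
    seed_positions = _seed_positions(candidates, seed_tissues) if seed_tissues else None
    rng = np.random.default_rng(seed)
    _, batches = _index_batches(len(candidates), k, M, mode, rng, seed_positions)
    ids = np.array(candidates, dtype=object)
    for batch in batches:
        for row in batch:
            yield CandidateSubset([str(s) for s in ids[row]])


def _seed_positions(candidates: Sequence[str], seed_tissues: Sequence[str]) -> np.ndarray:
    pos = {s: i for i, s in enumerate(candidates)}
    missing = [s for s in seed_tissues if s not in pos]
    if missing:
        raise ValueError(f"seed tissues not in candidate universe: {missing}")
    return np.array(sorted({pos[s] for s in seed_tissues}), dtype=np.intp)


# -- batched loss evaluation ----------------------------------------------


def _evaluate_index_batch(
    m: np.ndarray, targets_matrix: np.ndarray, idx: np.ndarray, a: float
) -> np.ndarray:
    """Loss of each subset in an index batch; +inf where no target is usable.

    ``m``: miRNA values over the candidate universe (n,).
    ``targets_matrix``: target values over the universe (n_targets, n).
    ``idx``: subset index rows (B, k).  Constant-vector targets are skipped
    per subset (denominator of p_neg shrinks), matching the scalar path.
    """
    mm = m[idx]                                   # (B, k)
    yy = targets_matrix[:, idx]                   # (T, B, k)
    mc = mm - mm.mean(axis=1, keepdims=True)
    yc = yy - yy.mean(axis=2, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = np.einsum("bk,tbk->tb", mc, yc)
        den = np.sqrt(np.einsum("bk,bk->b", mc, mc)[None, :] * np.einsum("tbk,tbk->tb", yc, yc))
        r = num / den                             # (T, B), NaN where undefined
    valid = ~np.isnan(r)
    n_valid = valid.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rbar = np.where(valid, r, 0.0).sum(axis=0) / n_valid
        p_neg = (r < 0).sum(axis=0) / n_valid
        losses = a * rbar + (1.0 - a) * (1.0 - p_neg)
    return np.where(n_valid > 0, losses, np.inf)


def search_best_subset(
    mirna_id: str,
    targets: Sequence[str],
    mirna_matrix: ExpressionMatrix,
    mrna_matrix: ExpressionMatrix,
    k: int,
    config: LossConfig,
    mode: str = "auto",
    seed_tissues: Sequence[str] | None = None,
    candidates: Sequence[str] | None = None,
    cutoff: float = DEFAULT_EXPRESSION_CUTOFF,
    rng: np.random.Generator | None = None,
) -> SubsetSearchResult:
    """Minimize the loss over subsets of size k for one miRNA.

    The candidate universe defaults to the tissues where the miRNA exceeds
    ``cutoff``; pass ``candidates`` to override.  Deterministic given the
    configuration seed; equal-loss ties go to the lexicographically smallest
    sorted sample-id tuple.
    """
    if mirna_matrix.sample_ids != mrna_matrix.sample_ids:
        raise ValueError("miRNA and mRNA matrices must share an identical sample list")
    if not targets:
        raise ValueError(f"no targets supplied for {mirna_id}")
    if candidates is None:
        candidates = candidate_tissues(mirna_id, mirna_matrix, cutoff, k_min=config.k_min)
    candidates = list(candidates)
    n = len(candidates)
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} candidate tissues for {mirna_id}")

    cols = mirna_matrix.sample_positions(candidates)
    m = mirna_matrix.row(mirna_id)[cols]
    t_cols = mrna_matrix.sample_positions(candidates)
    targets_matrix = mrna_matrix.rows(list(targets))[:, t_cols]

    seed_positions = _seed_positions(candidates, seed_tissues) if seed_tissues else None
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    effective_mode, batches = _index_batches(n, k, config.M, mode, rng, seed_positions)

    ids = candidates
    best_loss = np.inf
    best_ids: tuple[str, ...] | None = None
    n_evaluated = 0
    for idx in batches:
        losses = _evaluate_index_batch(m, targets_matrix, idx, config.a)
        n_evaluated += idx.shape[0]
        batch_min = losses.min()
        if batch_min > best_loss:
            continue
        contenders = np.flatnonzero(losses == batch_min)
        batch_best = min(tuple(sorted(ids[i] for i in idx[row])) for row in contenders)
        if batch_min < best_loss or (batch_min == best_loss and (best_ids is None or batch_best < best_ids)):
            best_loss = batch_min
            best_ids = batch_best
    if best_ids is None or not np.isfinite(best_loss):
        raise UndefinedCorrelationError(
            f"no evaluable subset of size {k} for {mirna_id} (all correlation profiles undefined)"
        )
    subset = CandidateSubset(best_ids)
    profile = correlation_profile(mirna_id, targets, mirna_matrix, mrna_matrix, subset)
    return SubsetSearchResult(
        mirna_id=mirna_id,
        k=k,
        best_subset=subset,
        best_loss=loss(profile, config.a),
        profile=profile,
        n_evaluated=n_evaluated,
        mode=effective_mode,
    )


def search_over_k(
    mirna_id: str,
    targets: Sequence[str],
    mirna_matrix: ExpressionMatrix,
    mrna_matrix: ExpressionMatrix,
    config: LossConfig,
    mode: str = "auto",
    seed_tissues: Sequence[str] | None = None,
    candidates: Sequence[str] | None = None,
    cutoff: float = DEFAULT_EXPRESSION_CUTOFF,
) -> tuple[list[SubsetSearchResult], SubsetSearchResult]:
    """Run the per-k search for k = k_min..k_max and pick the global best.

    Each k draws from an independent child stream of the configuration
    seed, so results do not depend on evaluation order.  The global best
    minimizes loss across k (ties: smaller k, then id tuple).
    """
    if candidates is None:
        candidates = candidate_tissues(mirna_id, mirna_matrix, cutoff, k_min=config.k_min)
    candidates = list(candidates)
    if config.k_max > len(candidates):
        raise ValueError(
            f"k_max={config.k_max} exceeds the {len(candidates)} candidate tissues for {mirna_id}"
        )
    ks = list(range(config.k_min, config.k_max + 1))
    children = np.random.SeedSequence(config.rng_seed).spawn(len(ks))
    results = [
        search_best_subset(
            mirna_id,
            targets,
            mirna_matrix,
            mrna_matrix,
            k,
            config,
            mode=mode,
            seed_tissues=seed_tissues,
            candidates=candidates,
            rng=np.random.default_rng(child),
        )
        for k, child in zip(ks, children)
    ]
    global_best = min(results, key=lambda r: (r.best_loss, r.k, r.best_subset.sample_ids))
    return results, global_best


def rank_tissues(per_k_results: Sequence[SubsetSearchResult]) -> TissueRanking:
    """Rank tissues by occurrence across the per-k best sets.

    Most frequent first; equal counts are ordered lexicographically by
    sample id and receive distinct ordinal ranks.
    """
    if not per_k_results:
        raise ValueError("need at least one search result to rank tissues")
    counts: Counter[str] = Counter()
    for result in per_k_results:
        counts.update(result.best_subset.sample_ids)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    entries = tuple(
        RankEntry(sample_id=s, occurrence_count=c, rank=i + 1) for i, (s, c) in enumerate(ordered)
    )
    return TissueRanking(entries=entries, source_k_values=tuple(r.k for r in per_k_results))


def extend_to_organs(
    selected: CandidateSubset,
    all_samples: Sequence[SampleAnnotation],
    mirna_id: str,
    mirna_matrix: ExpressionMatrix,
    cutoff: float = DEFAULT_EXPRESSION_CUTOFF,
) -> CandidateSubset:
    """Extend a selected subset to whole (organ, tumor/normal) classes.

    Takes every sample sharing an (organ, status) class with any selected
    sample, then drops those where the miRNA does not exceed the cutoff.
    Raises if fewer than two tissues survive.
    """
    by_id = {s.sample_id: s for s in all_samples}
    missing = [s for s in selected.sample_ids if s not in by_id]
    if missing:
        raise ValueError(f"selected tissues not among the annotated samples: {missing}")
    classes = {(by_id[s].organ, by_id[s].status) for s in selected.sample_ids}
    extended = [s.sample_id for s in all_samples if (s.organ, s.status) in classes]
    row = mirna_matrix.row(mirna_id)
    index = {s: i for i, s in enumerate(mirna_matrix.sample_ids)}
    kept = [s for s in extended if row[index[s]] > cutoff]
    if len(kept) < 2:
        raise ValueError(
            f"organ extension of {mirna_id} leaves {len(kept)} tissue(s) above cutoff {cutoff}"
        )
    return CandidateSubset(kept)
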