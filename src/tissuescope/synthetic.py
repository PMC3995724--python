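"""Synthetic paired miRNA/mRNA expression with planted tissue-restricted
down-regulation.

The generator emulates the statistical shape of a bulk tumor/normal
microarray panel: log2 intensities around a common baseline, samples
annotated as ``T|N_organ_k`` across an organ table mirroring an 89-sample,
11-organ cancer panel (68 tumor / 21 normal), and a known MTI catalog.  For
each synthetic miRNA a tissue subset is planted: inside it, every non-decoy
target is linearly down-regulated by the miRNA,

    y = baseline - beta * (m - baseline) + Normal(0, noise_sd),

giving a within-subset population correlation of
``rho = -beta / sqrt(beta**2 + noise_sd**2)``; outside the subset (and for
decoy targets everywhere) target values are independent baseline noise.
Decoys emulate validated interactions that are not anti-correlated in the
profiled tissues (e.g. protein-level-only repression).

The truth record (planted subsets, decoy flags) lets recovery be scored
exactly.  Fixed seed => bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .data_io import ExpressionMatrix, MTICatalog, SampleAnnotation

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "RecoveryScore",
    "generate",
    "score_recovery",
    "default_organ_table",
    "write_truth_json",
    "load_truth_json",
]

#: (organ, n_tumor, n_normal) mirroring an 89-sample 11-organ panel.
_DEFAULT_ORGANS: tuple[tuple[str, int, int], ...] = (
    ("colon", 7, 4),
    ("uterus", 10, 1),
    ("prostate", 6, 6),
    ("pancreas", 8, 1),
    ("ovary", 5, 0),
    ("lung", 5, 2),
    ("breast", 6, 3),
    ("bladder", 6, 1),
    ("mesothelioma", 8, 0),
    ("melanoma", 3, 0),
    ("kidney", 4, 3),
)


def default_organ_table() -> list[tuple[str, int, int]]:
    """The default 89-sample organ table (68 tumor, 21 normal)."""
    return [tuple(row) for row in _DEFAULT_ORGANS]


def _synthesize_organ_table(n_tissues: int) -> list[tuple[str, int, int]]:
    """Deterministic organ table for a non-default tissue count.

    Walks the default table's samples in order (tumors of an organ, then
    its normals) and takes the first ``n_tissues``, cycling if more than 89
    are requested (suffixing organ names on later cycles to keep sample ids
    unique).
    """
    counts: dict[tuple[str, str], int] = {}
    taken = 0
    cycle = 0
    while taken < n_tissues:
        suffix = "" if cycle == 0 else str(cycle + 1)
        for organ, n_tumor, n_normal in _DEFAULT_ORGANS:
            name = organ + suffix
            for status, n_status in (("tumor", n_tumor), ("normal", n_normal)):
                take = min(n_status, n_tissues - taken)
                if take > 0:
                    counts[(name, status)] = counts.get((name, status), 0) + take
                    taken += take
                if taken == n_tissues:
                    break
            if taken == n_tissues:
                break
        cycle += 1
    table: dict[str, list[int]] = {}
    for (organ, status), c in counts.items():
        entry = table.setdefault(organ, [0, 0])
        entry[0 if status == "tumor" else 1] += c
    return [(organ, t, n) for organ, (t, n) in table.items()]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator settings.

    Defaults describe the emulated study: 89 tissues over 11 organs,
    19 miRNAs with 10-43 validated targets each, planted subsets of 5
    tissues, strong down-regulation (beta=2) against moderate noise
    (noise_sd=0.5), baseline log2 intensity 9.0 and a 7.25 detection floor
    (truncation off by default so correlations stay well defined), with 10%
    decoy targets.
    """

    n_tissues: int = 89
    organs: tuple[tuple[str, int, int], ...] | None = None
    n_mirnas: int = 19
    targets_per_mirna: int | tuple[int, int] = (10, 43)
    planted_subset_size: int = 5
    beta: float = 2.0
    noise_sd: float = 0.5
    baseline_mean: float = 9.0
    detection_floor: float = 7.25
    apply_detection_floor: bool = False
    decoy_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tissues < 2:
            raise ValueError(f"need at least 2 tissues, got {self.n_tissues}")
        if not 2 <= self.planted_subset_size <= self.n_tissues:
            raise ValueError(
                f"planted_subset_size must lie in [2, n_tissues={self.n_tissues}], "
                f"got {self.planted_subset_size}"
            )
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be > 0, got {self.noise_sd}")
        if not 0.0 <= self.decoy_fraction <= 1.0:
            raise ValueError(f"decoy_fraction must lie in [0, 1], got {self.decoy_fraction}")
        if self.n_mirnas < 1:
            raise ValueError(f"n_mirnas must be >= 1, got {self.n_mirnas}")

    def resolved_organs(self) -> list[tuple[str, int, int]]:
        if self.organs is not None:
            table = [tuple(row) for row in self.organs]
            total = sum(t + n for _, t, n in table)
            if total != self.n_tissues:
                raise ValueError(f"organ table sums to {total} samples, but n_tissues={self.n_tissues}")
            return table
        if self.n_tissues == 89:
            return default_organ_table()
        return _synthesize_organ_table(self.n_tissues)

    def expected_correlation(self) -> float:
        """Population within-subset correlation: -beta / sqrt(beta^2 + sd^2)."""
        if self.beta == 0:
            return 0.0
        return -self.beta / float(np.sqrt(self.beta**2 + self.noise_sd**2))


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted subsets and decoy flags, sufficient to score recovery."""

    planted: dict[str, tuple[str, ...]] = field(default_factory=dict)
    decoys: dict[str, tuple[str, ...]] = field(default_factory=dict)


def _make_samples(organs: Sequence[tuple[str, int, int]]) -> list[SampleAnnotation]:
    samples = []
    for organ, n_tumor, n_normal in organs:
        samples.extend(SampleAnnotation("tumor", organ, i + 1) for i in range(n_tumor))
        samples.extend(SampleAnnotation("normal", organ, i + 1) for i in range(n_normal))
    return samples


def generate(spec: SyntheticSpec) -> tuple[ExpressionMatrix, ExpressionMatrix, MTICatalog, SyntheticTruth]:
    """Generate paired matrices, catalog and truth from a spec.

    miRNA values are Normal(baseline_mean, 1) per tissue.  Non-decoy target
    values follow the linear down-regulation model inside the miRNA's
    planted subset and independent baseline noise outside; decoy targets
    are independent everywhere.  If ``apply_detection_floor`` is set,
    values below the floor are truncated to it in both matrices.
    """
    rng = np.random.default_rng(spec.seed)
    samples = _make_samples(spec.resolved_organs())
    sample_ids = [s.sample_id for s in samples]
    n = len(samples)

    mirna_ids = [f"syn-mir-{i + 1}" for i in range(spec.n_mirnas)]
    mirna_values = spec.baseline_mean + rng.normal(0.0, 1.0, size=(spec.n_mirnas, n))

    if isinstance(spec.targets_per_mirna, int):
        n_targets = np.full(spec.n_mirnas, spec.targets_per_mirna, dtype=int)
    else:
        lo, hi = spec.targets_per_mirna
        n_targets = rng.integers(lo, hi + 1, size=spec.n_mirnas)

    gene_rows: list[np.ndarray] = []
    gene_ids: list[str] = []
    pairs: list[tuple[str, str]] = []
    planted: dict[str, tuple[str, ...]] = {}
    decoys: dict[str, tuple[str, ...]] = {}
    counter = 0
    for i, mirna in enumerate(mirna_ids):
        subset_positions = np.sort(rng.choice(n, size=spec.planted_subset_size, replace=False))
        planted[mirna] = tuple(sorted(sample_ids[p] for p in subset_positions))
        m = mirna_values[i]
        decoy_flags = rng.random(n_targets[i]) < spec.decoy_fraction
        mirna_decoys: list[str] = []
        for j in range(n_targets[i]):
            counter += 1
            gene = f"SYNG{counter:05d}"
            y = spec.baseline_mean + rng.normal(0.0, spec.noise_sd, size=n)
            if not decoy_flags[j]:
                y[subset_positions] = (
                    spec.baseline_mean
                    - spec.beta * (m[subset_positions] - spec.baseline_mean)
                    + rng.normal(0.0, spec.noise_sd, size=spec.planted_subset_size)
                )
            else:
                mirna_decoys.append(gene)
            gene_ids.append(gene)
            gene_rows.append(y)
            pairs.append((mirna, gene))
        decoys[mirna] = tuple(mirna_decoys)

    mrna_values = np.vstack(gene_rows)
    if spec.apply_detection_floor:
        mirna_values = np.maximum(mirna_values, spec.detection_floor)
        mrna_values = np.maximum(mrna_values, spec.detection_floor)

    mirna_matrix = ExpressionMatrix(mirna_ids, samples, mirna_values)
    mrna_matrix = ExpressionMatrix(gene_ids, samples, mrna_values)
    catalog = MTICatalog.from_pairs(pairs)
    return mirna_matrix, mrna_matrix, catalog, SyntheticTruth(planted=planted, decoys=decoys)


@dataclass(frozen=True)
class RecoveryScore:
    mirna_id: str
    jaccard: float
    exact: bool


def score_recovery(truth: SyntheticTruth, results: Sequence) -> dict[str, RecoveryScore]:
    """Jaccard overlap between planted and recovered subsets per miRNA.

    ``results`` are :class:`~tissuescope.search.SubsetSearchResult` objects
    (or anything with ``mirna_id`` and ``best_subset``).  Exact recovery
    means Jaccard 1 with matching sizes.
    """
    scores: dict[str, RecoveryScore] = {}
    for result in results:
        mirna = result.mirna_id
        if mirna not in truth.planted:
            raise KeyError(f"unknown miRNA id {mirna!r} in results")
        planted = set(truth.planted[mirna])
        recovered = set(result.best_subset.sample_ids)
        union = planted | recovered
        jaccard = len(planted & recovered) / len(union) if union else 1.0
        scores[mirna] = RecoveryScore(
            mirna_id=mirna,
            jaccard=jaccard,
            exact=jaccard == 1.0 and len(planted) == len(recovered),
        )
    return scores


def write_truth_json(truth: SyntheticTruth, path: str | Path) -> None:
    record = {
        "planted": {m: list(v) for m, v in sorted(truth.planted.items())},
        "decoys": {m: list(v) for m, v in sorted(truth.decoys.items())},
    }
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_truth_json(path: str | Path) -> SyntheticTruth:
    with open(path) as fh:
        record = json.load(fh)
    return SyntheticTruth(
        planted={m: tuple(v) for m, v in record["planted"].items()},
        decoys={m: tuple(v) for m, v in record["decoys"].items()},
    )
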