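"""Self-contained simulation studies of the search machinery.

Each study generates its own synthetic data, runs the package end to end
and returns summary rates.  They serve two roles: reproducible validation
runs (see ``scripts/acceptance.py``) and regression checks.  Problem sizes
are kept at desk scale — a few hundred thousand subset evaluations per
study — so a full run takes minutes on one core.

A note on recovery: under the linear-Gaussian generator the planted subset
is only partially identifiable.  Off-subset samples have expectation
(baseline, baseline) on both axes, which is exactly the centroid of the
within-subset regression line, so subsets mixing a few high-leverage
planted tissues with centroid-hugging background tissues can attain equal
or lower loss than the planted set, and smaller subsets yield
stochastically more extreme sample correlations (the best k tends to
k_min).  The recovery study therefore reports observed rates (exact
recovery, best-k selection, mean Jaccard overlap) rather than asserting
they are high; see docs/methods.md.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .core_stats import CandidateSubset, LossConfig, correlation_profile
from .evaluate import improvement, permutation_test
from .search import search_best_subset, search_over_k
from .synthetic import SyntheticSpec, generate, score_recovery

__all__ = [
    "oracle_equivalence_study",
    "subset_recovery_study",
    "null_calibration_study",
    "closed_form_correlation_study",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    """Independent 31-bit child seeds from one master seed."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def oracle_equivalence_study(seed: int = 0, n_instances: int = 20) -> dict:
    """Random-mode search vs exhaustive enumeration on small instances.

    Instances have 10-12 candidate tissues; for each k in {3, 4, 5} the
    random-mode search draws M = 10 * C(n, k) subsets and is scored a hit
    when it returns the exhaustive optimum.  Also verifies that exhaustive
    mode enumerates exactly C(n, k) subsets.
    """
    seeds = _child_seeds(seed, n_instances)
    hits = 0
    pairs = 0
    enumeration_exact = True
    for i, instance_seed in enumerate(seeds):
        n = 10 + i % 3
        spec = SyntheticSpec(
            n_tissues=n, n_mirnas=1, targets_per_mirna=8, planted_subset_size=4,
            beta=1.5, noise_sd=0.5, decoy_fraction=0.0, seed=instance_seed,
        )
        mirna_matrix, mrna_matrix, catalog, _ = generate(spec)
        targets = catalog.targets("syn-mir-1")
        for k in (3, 4, 5):
            C = math.comb(n, k)
            config = LossConfig(a=0.4, M=10 * C, k_min=3, k_max=5, rng_seed=instance_seed + k)
            exhaustive = search_best_subset(
                "syn-mir-1", targets, mirna_matrix, mrna_matrix, k, config,
                mode="exhaustive", candidates=mirna_matrix.sample_ids,
            )
            enumeration_exact &= exhaustive.n_evaluated == C
            random_mode = search_best_subset(
                "syn-mir-1", targets, mirna_matrix, mrna_matrix, k, config,
                mode="random", candidates=mirna_matrix.sample_ids,
            )
            hits += random_mode.best_subset == exhaustive.best_subset
            pairs += 1
    return {
        "hit_rate": hits / pairs,
        "n_pairs": pairs,
        "enumeration_exact": enumeration_exact,
    }


def subset_recovery_study(seed: int = 0, n_replicates: int = 100) -> dict:
    """Planted-subset recovery at the generator's reference conditions.

    Per replicate: 30 tissues, one miRNA with 10 targets, a planted subset
    of 5, beta = 2, noise_sd = 0.5.  Measures how often exhaustive search
    at k = 5 returns exactly the planted subset, how often the k-sweep
    (k = 3..8, M = 100,000) picks k = 5 as global best, and the mean
    Jaccard overlap of the exhaustive k = 5 optimum with the truth.
    """
    seeds = _child_seeds(seed, n_replicates)
    exact = 0
    k_hits = 0
    jaccards = []
    for replicate_seed in seeds:
        spec = SyntheticSpec(
            n_tissues=30, n_mirnas=1, targets_per_mirna=10, planted_subset_size=5,
            beta=2.0, noise_sd=0.5, seed=replicate_seed,
        )
        mirna_matrix, mrna_matrix, catalog, truth = generate(spec)
        targets = catalog.targets("syn-mir-1")
        config = LossConfig(a=0.4, M=100_000, k_min=3, k_max=8, rng_seed=replicate_seed)
        at_true_k = search_best_subset(
            "syn-mir-1", targets, mirna_matrix, mrna_matrix, 5, config,
            mode="exhaustive", candidates=mirna_matrix.sample_ids,
        )
        score = score_recovery(truth, [at_true_k])["syn-mir-1"]
        exact += score.exact
        jaccards.append(score.jaccard)
        _, best = search_over_k(
            "syn-mir-1", targets, mirna_matrix, mrna_matrix, config,
            candidates=mirna_matrix.sample_ids,
        )
        k_hits += best.k == 5
    return {
        "exact_recovery_rate": exact / n_replicates,
        "k_selection_rate": k_hits / n_replicates,
        "mean_jaccard": float(np.mean(jaccards)),
        "n_replicates": n_replicates,
    }


def null_calibration_study(seed: int = 0, n_replicates: int = 200, B: int = 199) -> dict:
    """Permutation p-values and S - A under the null (beta = 0).

    Per replicate: null data, a uniformly drawn "selected" subset of 5 of
    30 tissues, a B-draw permutation test and the improvement record.
    Returns the KS comparison of the p-values against Uniform(0, 1) and the
    mean S - A.
    """
    seeds = _child_seeds(seed, n_replicates)
    p_values = []
    deltas = []
    for replicate_seed in seeds:
        spec = SyntheticSpec(
            n_tissues=30, n_mirnas=1, targets_per_mirna=10, planted_subset_size=5,
            beta=0.0, noise_sd=0.5, decoy_fraction=0.0, seed=replicate_seed,
        )
        mirna_matrix, mrna_matrix, catalog, _ = generate(spec)
        targets = catalog.targets("syn-mir-1")
        rng = np.random.default_rng(replicate_seed + 1)
        selected = CandidateSubset(rng.choice(mirna_matrix.sample_ids, size=5, replace=False))
        report = permutation_test(
            "syn-mir-1", targets, mirna_matrix, mrna_matrix, selected,
            B=B, seed=replicate_seed + 2, candidates=mirna_matrix.sample_ids,
        )
        p_values.append(report.empirical_p)
        record = improvement("syn-mir-1", targets, mirna_matrix, mrna_matrix, selected)
        deltas.append(record.delta)
    ks = stats.kstest(p_values, "uniform")
    return {
        "ks_statistic": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
        "mean_delta": float(np.mean(deltas)),
        "n_replicates": n_replicates,
    }


def closed_form_correlation_study(seed: int = 0, n_draws: int = 1000) -> dict:
    """Within-planted-subset correlations vs the generator's closed form.

    The population correlation inside the planted subset is
    rho = -beta / sqrt(beta^2 + noise_sd^2).  The empirical mean of the
    sample correlation is compared against rho.  Two design points keep the
    comparison coherent: each draw uses its own miRNA (one target per
    miRNA), so draws are independent and the iid standard error is valid —
    targets sharing one miRNA realization would be strongly clustered and
    the nominal SE would understate the Monte-Carlo error; and the subset
    is kept large (80 tissues) with a moderate effect (beta = 0.5,
    noise_sd = 1) so the finite-sample bias of Pearson's r,
    ~ rho (1 - rho^2) / (2 n), stays well below that error.
    """
    spec = SyntheticSpec(
        n_tissues=89, n_mirnas=n_draws, targets_per_mirna=1, planted_subset_size=80,
        beta=0.5, noise_sd=1.0, decoy_fraction=0.0, seed=seed,
    )
    mirna_matrix, mrna_matrix, catalog, truth = generate(spec)
    correlations: list[float] = []
    for mirna in catalog.mirnas:
        subset = CandidateSubset(truth.planted[mirna])
        profile = correlation_profile(mirna, catalog.targets(mirna), mirna_matrix, mrna_matrix, subset)
        correlations.extend(profile.correlations)
    correlations = correlations[:n_draws]
    expected = spec.expected_correlation()
    empirical = float(np.mean(correlations))
    se = float(np.std(correlations, ddof=1) / np.sqrt(len(correlations)))
    return {
        "empirical_mean": empirical,
        "expected": expected,
        "abs_error": abs(empirical - expected),
        "three_se": 3 * se,
        "n_draws": len(correlations),
    }
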