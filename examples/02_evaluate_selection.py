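"""Quantify how much a selected tissue subset improves anti-correlation.

Computes the S - A improvement (mean miRNA--target correlation over the
selected tissues minus the mean over all tissues), a permutation test
against random same-size tissue sets, and the skewness of the correlation
densities.
"""

from tissuescope import (
    CandidateSubset,
    LossConfig,
    SyntheticSpec,
    density_comparison,
    correlation_profile,
    generate,
    improvement,
    permutation_test,
    search_best_subset,
)

spec = SyntheticSpec(
    n_tissues=30, n_mirnas=1, targets_per_mirna=10, planted_subset_size=5,
    beta=2.0, noise_sd=0.5, decoy_fraction=0.0, seed=7,
)
mirna_matrix, mrna_matrix, catalog, truth = generate(spec)
targets = catalog.targets("syn-mir-1")

config = LossConfig(a=0.4, M=20_000, k_min=3, k_max=8, rng_seed=1)
result = search_best_subset(
    "syn-mir-1", targets, mirna_matrix, mrna_matrix, 5, config,
    mode="exhaustive", candidates=mirna_matrix.sample_ids,
)

record = improvement("syn-mir-1", targets, mirna_matrix, mrna_matrix, result.best_subset)
print(f"A (mean correlation, all {mirna_matrix.shape[1]} tissues): {record.all_tissue_mean:+.3f}")
print(f"S (mean correlation, {result.best_subset.n_A} selected tissues): {record.selected_mean:+.3f}")
print(f"S - A improvement: {record.delta:+.3f}  (strongly negative = selection found")
print("tissues where the targets are anti-correlated with the miRNA)")

report = permutation_test(
    "syn-mir-1", targets, mirna_matrix, mrna_matrix, result.best_subset,
    B=999, seed=2, candidates=mirna_matrix.sample_ids,
)
print(f"\npermutation test: observed loss {report.observed_loss:+.4f}, "
      f"empirical p = {report.empirical_p:.4f} (B = {report.B})")
print(f"  note: {report.note}")

all_profile = correlation_profile(
    "syn-mir-1", targets, mirna_matrix, mrna_matrix, CandidateSubset(mirna_matrix.sample_ids)
)
table, skewness = density_comparison(
    [("all tissues", all_profile.correlations), ("selected", result.profile.correlations)]
)
print(f"\ncorrelation-density skewness: all tissues {skewness['all tissues']:+.2f}, "
      f"selected {skewness['selected']:+.2f}")
print("A right-skewed (positive) selected density means most correlations pile up")
print("near -1 with a tail toward 0: the signature of tissue-restricted down-regulation.")
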