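"""Find the MTI-supported tissues of a synthetic miRNA.

Generates a 30-tissue study with one miRNA whose 10 validated targets are
down-regulated in a planted 5-tissue subset, then runs the correlation
loss function algorithm over subset sizes k = 3..8 and ranks tissues by
how often they occur in the per-k best sets.
"""

from tissuescope import (
    LossConfig,
    SyntheticSpec,
    generate,
    rank_tissues,
    search_over_k,
)

spec = SyntheticSpec(
    n_tissues=30, n_mirnas=1, targets_per_mirna=10, planted_subset_size=5,
    beta=2.0, noise_sd=0.5, decoy_fraction=0.0, seed=7,
)
mirna_matrix, mrna_matrix, catalog, truth = generate(spec)
targets = catalog.targets("syn-mir-1")

config = LossConfig(a=0.4, M=20_000, k_min=3, k_max=8, rng_seed=1)
results, best = search_over_k(
    "syn-mir-1", targets, mirna_matrix, mrna_matrix, config, candidates=mirna_matrix.sample_ids
)

print("per-k best losses (lower = stronger anti-correlation with more negative targets):")
for r in results:
    print(f"  k={r.k}  loss={r.best_loss:+.4f}  mean_corr={r.profile.mean_corr:+.3f}  "
          f"p_neg={r.profile.p_neg:.2f}  mode={r.mode}")

print(f"\nglobal best: k={best.k}, tissues = {', '.join(best.best_subset.sample_ids)}")
print(f"planted truth:        {', '.join(truth.planted['syn-mir-1'])}")

ranking = rank_tissues(results)
print("\ntissue ranking across the per-k best sets (occurrences out of 6 sets):")
for entry in ranking.entries[:8]:
    print(f"  rank {entry.rank}: {entry.sample_id}  ({entry.occurrence_count}x)")
print("\nTissues recurring across many k are the robust MTI-supported candidates;")
print("small-k optima overfit sample correlations, so the truth overlaps but")
print("rarely equals the single global-best subset.")
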