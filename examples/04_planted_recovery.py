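"""Score how well exhaustive search recovers a planted tissue subset.

Also checks the generator against its own closed form: inside the planted
subset the population miRNA--target correlation is
rho = -beta / sqrt(beta^2 + noise_sd^2).
"""

import numpy as np

from tissuescope import (
    CandidateSubset,
    LossConfig,
    SyntheticSpec,
    correlation_profile,
    generate,
    score_recovery,
    search_best_subset,
)

spec = SyntheticSpec(
    n_tissues=30, n_mirnas=3, targets_per_mirna=10, planted_subset_size=5,
    beta=2.0, noise_sd=0.5, decoy_fraction=0.0, seed=21,
)
mirna_matrix, mrna_matrix, catalog, truth = generate(spec)
config = LossConfig(a=0.4, M=100_000, k_min=3, k_max=8, rng_seed=3)

results = []
for mirna in catalog.mirnas:
    results.append(
        search_best_subset(
            mirna, catalog.targets(mirna), mirna_matrix, mrna_matrix, 5, config,
            mode="exhaustive", candidates=mirna_matrix.sample_ids,
        )
    )
scores = score_recovery(truth, results)
print("exhaustive search at the true subset size (k = 5):")
for mirna, score in scores.items():
    print(f"  {mirna}: Jaccard overlap with planted truth = {score.jaccard:.2f}, exact = {score.exact}")
print("Partial overlap is expected: background tissues sit at the centroid of the")
print("within-subset regression, so some mixed subsets match the planted loss.")

rho = spec.expected_correlation()
observed = []
for mirna in catalog.mirnas:
    profile = correlation_profile(
        mirna, catalog.targets(mirna), mirna_matrix, mrna_matrix,
        CandidateSubset(truth.planted[mirna]),
    )
    observed.extend(profile.correlations)
print(f"\nclosed form rho = {rho:+.3f}; "
      f"mean within-planted-subset correlation = {np.mean(observed):+.3f} over {len(observed)} targets")
print("(agreement confirms the generator implements the stated linear-Gaussian model)")
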