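# tissuescope

Tools for locating **MTI-supported tissues**: the tissue subsets in which a
microRNA and its experimentally validated target genes are strongly
anti-correlated, indicating where the miRNA's down-regulation is actually
functional.

miRNAs repress their targets, so across tissues where an miRNA--target
interaction (MTI) is active, miRNA and target expression should correlate
negatively.  In practice, correlations computed over *all* profiled tissues
hover near zero — repression is tissue-specific.  `tissuescope` searches for
the subset of tissues that makes the anti-correlation signal emerge.

## The method

For an miRNA *m* with validated targets *y₁ … y_N* and a candidate tissue
subset *A* (drawn from the tissues where *m*'s log2 expression exceeds a
detection cutoff, 7.25 by default), let

- *r̄_A* — mean Pearson correlation ρ(m, yᵢ; A) over the N targets,
- *p_neg* — proportion of those correlations that are strictly negative.

The subset is scored with the loss

```
L_a(A) = a · r̄_A + (1 − a) · (1 − p_neg),      0 < a < 1   (default a = 0.4)
```

which is minimized when the targets are, on average, strongly negatively
correlated with the miRNA **and** nearly all individual correlations are
negative.  Because enumerating every subset of every size is infeasible, the
*correlation loss function algorithm* draws M random k-subsets per subset
size k (default M = 100,000, k = 3…15), keeps the per-k minimizer, switches
to exhaustive enumeration whenever C(n, k) ≤ M, and selects the global best
across k.  Tissues are then ranked by how often they appear across the
per-k best sets — a more stable readout than any single optimal subset.
Selected subsets can be extended to whole (organ, tumor/normal) classes and
assessed with the S − A improvement (selected-tissue mean correlation minus
all-tissue mean), a tissue-resampling permutation test, and overlaid
correlation densities.

A fully seeded synthetic-data generator plants tissue-restricted linear
down-regulation into paired miRNA/mRNA matrices (89 tumor/normal samples
over 11 organs by default), so every stage is testable without external
downloads.

## Worked example

```python
from tissuescope import LossConfig, SyntheticSpec, generate, rank_tissues, search_over_k

spec = SyntheticSpec(n_tissues=30, n_mirnas=1, targets_per_mirna=10,
                     planted_subset_size=5, beta=2.0, noise_sd=0.5,
                     decoy_fraction=0.0, seed=7)
mirna, mrna, catalog, truth = generate(spec)
config = LossConfig(a=0.4, M=20_000, k_min=3, k_max=8, rng_seed=1)
results, best = search_over_k("syn-mir-1", catalog.targets("syn-mir-1"),
                              mirna, mrna, config, candidates=mirna.sample_ids)
for r in results:
    print(f"k={r.k}  loss={r.best_loss:+.4f}  mean_corr={r.profile.mean_corr:+.3f}")
print("ranking:", [(e.sample_id, e.occurrence_count) for e in rank_tissues(results).entries[:4]])
```

prints

```
k=3  loss=-0.3989  mean_corr=-0.997
k=4  loss=-0.3967  mean_corr=-0.992
k=5  loss=-0.3915  mean_corr=-0.979
k=6  loss=-0.3877  mean_corr=-0.969
k=7  loss=-0.3823  mean_corr=-0.956
k=8  loss=-0.3803  mean_corr=-0.951
ranking: [('N_colon_1', 6), ('T_uterus_3', 6), ('N_prostate_2', 5), ('N_colon_4', 3)]
```

All six per-k optima reach p_neg = 1 with mean correlations near −1, and the
three top-ranked tissues (occurring in 5–6 of the 6 per-k best sets) are all
members of the planted 5-tissue subset.  The `examples/` directory has one
narrative script per capability: the search and ranking shown above,
selection evaluation (S − A, permutation test, density skewness), organ
extension, and planted-subset recovery scoring.

There is also a thin CLI for file-based workflows:

```sh
tissuescope simulate --spec spec.yaml --out data/
tissuescope search --mirna-expr data/mirna_expression.tsv \
    --mrna-expr data/mrna_expression.tsv --mti data/mti_catalog.tsv \
    --a 0.4 --m 100000 --k-min 3 --k-max 15 --seed 7 --out results/
tissuescope evaluate --mirna-expr ... --mrna-expr ... --mti ... \
    --result results/<mirna>.best.json --out eval/
```

Expression inputs are plain TSV/CSV (features × samples) with sample ids in
the `T|N_organ_replicate` form (e.g. `N_uterus_8`); MTI catalogs are
delimited tables with miRTarBase-style columns.

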