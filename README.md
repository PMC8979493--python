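# sdx

Scores **differential dependencies** from perturbation-screen score
matrices (DepMap-style genes × cell-lines CERES scores) and finds
**approximately mutually exclusive sets of binary features** (annotated
mutations, cancer types) associated with each of them.

The method has three stages:

1. **Scoring** (`sdx.scoring`) — each gene's score profile is z-scored,
   prefiltered by an n-sigma outlier criterion, and tested for
   bimodality by comparing one- vs two-component Student-t mixture fits
   with BIC. For two-component ("2C") genes, a gaussian mixture yields a
   per-sample *2C score*: the log ratio of posterior probabilities of
   the higher- vs lower-mean component. The minority component is the
   *responsive* one; its sign defines the profile's direction
   (increased/decreased dependency). A NormLRT comparison metric
   (skew-t vs gaussian likelihood ratio) is also provided.
2. **Feature construction** (`sdx.features`) — annotated mutations are
   grouped per gene into Activating / Inactivating / Other binary
   features `GENE(A)/(I)/(O)`; sample metadata adds mutually exclusive
   cancer-type rows.
3. **Association** (`sdx.optimize`, `sdx.significance`) — feature sets
   are scored with an exclusivity-penalized, phenotype-weighted coverage
   weight (same-gene I/O co-occurrence is exempt from the penalty — the
   two-hit exception) and optimized **exactly**, either with a MILP
   (HiGHS via `scipy.optimize.milp`) or by vectorized enumeration.
   Selected sets pass a per-feature conditional permutation test (model
   selection), then an empirical significance test against optimal
   weights on curveball (fixed row/column sums) randomizations of the
   full mutation matrix, with Benjamini-Hochberg FDR across profiles.

`sdx.synthetic` generates seeded cohorts with known ground truth
(planted mutually exclusive feature sets in responsive samples,
overdispersed background mutations) so the whole pipeline is testable
offline.

## CLI

```sh
# generate a synthetic cohort with a truth manifest
sdx simulate --spec cohort.yaml --out cohort/ --seed 1

# stage-by-stage
sdx score --dependency cohort/dependency.csv --n-sigma 2 --out scores/
sdx features --mutations cohort/mutations.tsv --metadata cohort/metadata.csv --out features.tsv
sdx associate --scores scores/two_component_scores.csv --features cohort/features.csv --k 3

# full pipeline from a YAML config (RunConfig fields)
sdx run --config run.yaml
```

A minimal `run.yaml`:

```yaml
dependency_path: cohort/dependency.csv
mutation_path: cohort/mutations.tsv
metadata_path: cohort/metadata.csv   # optional; enables cancer-type features
out_dir: out/
n_sigma: 6.0            # outlier prefilter (z-units)
k: null                 # max set size; defaults: 3 mutations-only, 5 with types
n_model_select: 10000   # per-feature permutations
n_significance_max: 500000
alpha_remove: 1.0e-4
fdr_threshold: 0.2
seed: 1
```

Outputs: `differential_dependencies.tsv` (per-gene BIC decision,
direction, responsive count), `two_component_scores.csv` (profiles ×
samples 2C scores), `associations.tsv` (feature set, weight,
per-feature and set p-values, q), and `run_manifest.json`. Every output
carries a `#` manifest line with version, config hash, and seed; runs
are bitwise reproducible given the same config and seed.

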