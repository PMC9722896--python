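# srsboot

Bootstrapped evaluation of clinical/radiomic models that predict
per-lesion progression after stereotactic radiosurgery (SRS) of brain
metastases. The package provides, as tested reusable components:

- **`srsboot.cohort`** — a synthetic cohort generator (99 patients,
  1–3 lesions each, 12 clinical features, 107 radiomic-like continuous
  features with configurable volume correlations, 5 scanner models with
  optional planted domain shifts, logistic outcome model) plus the
  diameter-product progression rule;
- **`srsboot.preprocessing`** — Z-score normalization over a brain mask
  with ±3 SD clipping, trilinear isotropic resampling, fixed-bin-count
  discretization;
- **`srsboot.engine`** — the 250-repetition patient-level bootstrap:
  per-repetition greedy inter-feature correlation filtering, random
  decision forest fitting, and recording of test-set, out-of-bag and
  resubstitution probabilities plus raw importances;
- **`srsboot.metrics`** — pooled ROC/AUC, the `.632+` bootstrap
  correction in AUC space, out-of-bag upper-left operating-point
  selection and transfer (MCR/FNR/FPR), percentile confidence intervals,
  vertical-average ROC bands;
- **`srsboot.volume_filter`** — volume-decorrelation feature removal
  (rank-sum/Kruskal–Wallis for categoricals, dual Pearson tests against
  volume and its cubic root for continuous features, Bonferroni
  α = 0.05/118, threshold sweep), the primary-site variant, and the
  univariate association tests;
- **`srsboot.importance`** — normalized cross-repetition importance
  aggregation with the "highly important" cutoff (score > 0.75);
- **`srsboot.stratify`** — stratified re-aggregation of pooled
  probabilities by primary site / volume group (7.5 cc cut) / scanner
  model, and scanner-pair subset experiments;
- **`srsboot.runner`** — study orchestration from a YAML config and
  replication of the metric suite from serialized probability tables.

## CLI

```sh
srsboot synthesize --seed 1 --n-patients 99 --out cohort.tsv
srsboot filter cohort.tsv --threshold 0.25 --out decisions.tsv
srsboot run cohort.tsv --features both --reps 250 --seed 1 --out runout/
srsboot stratify cohort.tsv --by volume --reps 50 --seed 1 --out volume.tsv
srsboot sweep cohort.tsv --reps 50 --seed 1 --out sweep.tsv
srsboot replicate runout/probabilities.tsv --out metrics.tsv
srsboot report --config study.yaml
```

Cohorts are plain TSV (one row per lesion: `patient_id`, `bm_id`, 12
clinical columns, `f001`…`f107`, `scanner`, `label`) with a JSON config
sidecar; probability tables are TSV with columns
`rep, bm_id, partition ∈ {test, oob, apparent}, probability, label`, so
externally supplied predictions can be replicated without refitting.

A study YAML for `srsboot report` looks like:

```yaml
seed: 1
experiments: [feature_sets, stratify_volume, volume_sweep, importance]
engine: {n_reps: 250, n_trees: 500}
cohort: {n_patients: 99}
out_dir: study_out
```

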