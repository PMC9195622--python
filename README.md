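# alffpipe

A reproducible pipeline for classifying paired (pre/post) resting-state
scans from region-wise ALFF (amplitude of low-frequency fluctuations)
features, with a synthetic-data generator providing ground truth.

Stages:

1. **synthetic** — paired BOLD-like 4D cohorts with a parcellation atlas,
   rigid-body motion traces, behavioral scores, and a truth record; a
   configurable standardized effect is planted in chosen regions.
2. **alff** — framewise-displacement QC (Power FD, subjects excluded above a
   mean-FD threshold), linear detrending, voxel-wise ALFF (mean in-band
   amplitude spectrum, 0.01–0.08 Hz), whole-brain standardization, atlas
   parcel averaging, and feature-matrix assembly (+1 = post, −1 = pre).
3. **selection** — leave-one-out paired-t screening (union of regions with
   p < α), residualization against the CFMT confound, and accuracy-driven
   recursive feature elimination (batch removal of every feature whose
   single removal does not decrease LOOCV-SVM accuracy).
4. **classify** — linear soft-margin SVM (C configurable, default 1),
   leave-one-subject-out (or per-scan) CV, confusion-count metrics, ROC/AUC,
   and a label-permutation significance test (paired subject flips, or
   independent per-scan relabeling).
5. **stats** — pre/post behavioral comparisons (Mann-Whitney, optional
   Wilcoxon) and brain–behavior delta correlations with Benjamini–Hochberg
   FDR control.
6. **pipeline** — end-to-end orchestration into a schema-validated JSON
   report; fully seeded and bit-reproducible.

Methodological leakage in the published-style procedure (selection seeing
all the data before a final-features permutation) is kept available as the
default but measurable: `selection_mode="nested"` re-runs selection inside
each outer fold, and `perm_scope="full_pipeline"` re-runs selection per
permutation.

## CLI

```sh
alffpipe simulate --config syn.json --out cohort/     # synthetic cohort
alffpipe alff --img cohort/sub-001_pre_bold.nii.gz \
    --atlas cohort/atlas.nii.gz \
    --motion cohort/sub-001_pre_motion.txt --out alff_out/
alffpipe select --features fm.tsv --behavior behavior.csv --out sel.json
alffpipe classify --features fm.tsv --selection sel.json \
    --behavior behavior.csv --permutations 1000 --seed 7 --out clf_out/
alffpipe behavior-stats --behavior behavior.csv
alffpipe brain-behavior --features fm.tsv --behavior behavior.csv \
    --selection sel.json --q 0.05 --out bb.csv
alffpipe run --config run.json --out run_out/          # whole pipeline
```

`run.json` mirrors `alffpipe.pipeline.RunConfig` (band, FD threshold, α,
selection mode, C, permutation count/pairing/scope, seeds, output dir);
omitted fields take the defaults.

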