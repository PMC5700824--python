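# Full-pipeline configuration for `vbm-motormap run-all --config config.yaml`.
# Omit gm4d/clinical/atlas to run on a generated synthetic cohort instead.

out_dir: vbm_out
force: false
seed: 42
alpha: 0.05
n_perm: 1000
tail: one_neg          # negative one-tailed: GM loss with increasing severity
connectivity: 18
min_mean_intensity: 0.05
svc_regions: [caudate_L, caudate_R, putamen_L, putamen_R]

# Real-data inputs (all four required together):
# gm4d: cohort/gm4d.nii.gz          # 4-D NIfTI, subjects on the last axis
# clinical: cohort/clinical.csv     # subject_id, visit_date (ISO-8601),
#                                   # item_1..item_18, age, sex, on_medication
# atlas: cohort/atlas.nii.gz        # integer labels on the same grid
# atlas_names: cohort/atlas_names.tsv
# scan_date: "2015-06-01"           # visit nearest this date is scored

# Synthetic cohort (used when gm4d is absent):
synthetic:
  n: 364
  shape: [40, 48, 40]
  spacing_mm: 4.0
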