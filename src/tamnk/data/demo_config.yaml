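# Demo configuration: fully synthetic single-cell run plus survival cohort.
# The simulated gene universe is small (~300 genes), so the QC gene floor is
# lowered accordingly; all other knobs keep their analysis defaults.
seed: 0
simulate:
  single_cell:
    n_cells_per_type: {M0: 60, M1: 60, M2: 60, MONOCYTE: 60, NK_LIKE: 60, TUMOR: 60}
    n_background_genes: 200
    marker_log2_fc: 3.0
    nb_dispersion: 0.1
    lib_size_mean: 5000
    mito_fraction_mean: 0.05
    doublet_rate: 0.05
  cohort:
    n_patients: 120
    true_hr_low_vs_high: 2.0
    score_shift: 1.0
    baseline_hazard: 0.1
    censor_rate: 0.2
qc:
  min_genes: 50
  max_genes: 50000
  max_umi: 30000
  max_pct_mito: 20
  scale: 10000
enrich:
  cell_method: ssgsea
  cell_kernel: none
  patient_method: zscore
score:
  mode: difference
  margin: 0.0
lr:
  sender: M2
  receiver: NK_LIKE
  combine: mean
survive:
  q_low: 0.1
  q_high: 0.9
  n_perm: 200
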