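# End-to-end synthetic demo: one planted 40-gene x 60-sample block whose
# first three genes also drive the simulated hazard.
seed: 42
simulate:
  n_genes: 300
  n_samples: 400
  noise_sd: 1.0
  tumor_fraction: 0.35
  blocks:
    - {n_genes: 40, n_samples: 60, shift: 3.0, direction: up}
  survival:
    n_signal_genes: 3
    beta: 0.5
    baseline_rate: 0.001
    censor_rate: 0.0002
bicluster:
  p: 0.15
  direction: high
  j_min: 0.4
  min_genes: 20
  min_samples: 40
enrich:
  fdr: 0.01
risk:
  alpha: 1.0
  cv_folds: 10
stratify:
  scheme: median
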