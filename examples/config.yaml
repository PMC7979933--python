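# Small end-to-end run configuration: a 26x26 landscape at 800 m with 220
# profiles, the published protocol thresholds, and two climate scenarios.
seed: 7
outdir: socgwr_run
nx: 26
ny: 26
cell_size: 800.0
n_regions: 4
smoothness: 4.0
n_obs: 220
layers_per_profile: 5
lambda_true: 0.5
noise_sd: 0.3
iqr_k: 1.5
corr_threshold: 0.70
alpha: 0.05
train_fraction: 0.75
kernel: bisquare
decades: [2030, 2040, 2050]
scenarios:
  ssp_low:
    temp_delta_per_decade: 0.1
    precip_factor_per_decade: 1.0
  ssp_high:
    temp_delta_per_decade: 0.5
    precip_factor_per_decade: 0.97
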