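# Demo pipeline configuration: small simulated organoid, packaged synthetic
# cohort fixtures, working threshold 30%.
seed: 1
out_dir: obp_demo_out
n_cells: 12
fibroblast_fraction: 0.3
apoptotic_fraction: 0.0
shell_radius_um: 30.0
separation_um: 16.0
min_nucleus_volume_um3: 65.0
thresholds: [10, 20, 30, 40]
default_threshold_pct: 30.0
ca199_cutoff: 35.0
landmark_months: 32.0
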