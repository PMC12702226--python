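# Demo configuration: 6 synthetic patients, 4 weeks of weekly ASL scans.
output_dir: scratch/demo_run
seed: 1
log_level: INFO

# quantification (single-PLD model constants)
alpha: 0.59             # labelling efficiency for the final maps
alpha_consensus: 0.85   # maps are fitted here first, then rescaled
use_measured_alpha: true
lambda_bp: 0.9          # ml/g
t1_blood: 1350.0        # ms
tau: 1800.0             # ms
pld: 2000.0             # ms
m0_threshold_frac: 0.1

# region analysis
connectivity: 26
min_hcbf_volume_cm3: 1.0

# synthetic cohort
n_patients: 6
n_weeks: 4
grid_shape: [40, 40, 20]
voxel_size_mm: [4.0, 4.0, 8.0]
alpha_true: 0.59
noise_sd: 0.002         # frame noise as a fraction of M0
weekly_hot_shrink: 0.8
ll_noise_sd_frac: 0.01

save_nifti: false
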