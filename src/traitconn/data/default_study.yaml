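# Shipped default study configuration.
#
# The cohort and inference constants below define the canonical study design
# this pipeline emulates; a test asserts they match the package's canonical
# constants so this file cannot drift from the code defaults.

n_subjects: 39            # cohort size of the emulated resting-state study
runs_per_subject:         # distribution of retained resting scans, 1..5 per subject
  1: 0.2
  2: 0.2
  3: 0.4
  4: 0.1
  5: 0.1
grid_shape: [24, 28, 24]  # desk-scale analysis grid (full pipeline geometry is configurable)
voxel_size_mm: 4.0
n_volumes: 197            # EPI volumes per run
tr_seconds: 2.0           # repetition time

# Five-factor (NEO domain) score moments on the raw-score scale, order N,E,O,A,C
trait_means: [78.0, 119.0, 128.0, 125.0, 122.0]
trait_sds: [28.0, 20.0, 21.0, 15.0, 22.0]
trait_corr:               # near-orthogonal domains
- [1.0, 0.0, 0.0, 0.0, 0.0]
- [0.0, 1.0, 0.0, 0.0, 0.0]
- [0.0, 0.0, 1.0, 0.0, 0.0]
- [0.0, 0.0, 0.0, 1.0, 0.0]
- [0.0, 0.0, 0.0, 0.0, 1.0]
age_range: [19.0, 45.0]
male_fraction: 0.46153846153846156   # 18 of 39

# Spherical seed regions, MNI mm, 8 mm diameter: one anterior-cingulate-like
# midline seed and a precuneus-like left/right pair
seeds:
- {name: acc,   center_mm: [0.0, 36.0, 8.0],    diameter_mm: 8.0, hemisphere: bilateral}
- {name: pcu_l, center_mm: [-8.0, -40.0, 20.0], diameter_mm: 8.0, hemisphere: left}
- {name: pcu_r, center_mm: [8.0, -40.0, 20.0],  diameter_mm: 8.0, hemisphere: right}

# Planted ground-truth couplings: one variable-valence trait association per
# domain (disjoint targets), two invariant-positive connections (one carrying
# a weaker secondary openness association) and one invariant-negative one.
effects:
- {seed_name: acc,   name: var_neuroticism,       center_mm: [-24.0, 16.0, -12.0], radius_mm: 8.0,
   baseline_coupling: 0.0,  trait_slope: {neuroticism: 0.006},       valence_class: variable}
- {seed_name: acc,   name: var_extraversion,      center_mm: [28.0, 20.0, 4.0],    radius_mm: 8.0,
   baseline_coupling: 0.0,  trait_slope: {extraversion: 0.0085},     valence_class: variable}
- {seed_name: pcu_l, name: var_openness,          center_mm: [-24.0, -32.0, 4.0],  radius_mm: 8.0,
   baseline_coupling: 0.0,  trait_slope: {openness: 0.008},          valence_class: variable}
- {seed_name: pcu_r, name: var_agreeableness,     center_mm: [20.0, -24.0, 12.0],  radius_mm: 8.0,
   baseline_coupling: 0.0,  trait_slope: {agreeableness: 0.011},     valence_class: variable}
- {seed_name: acc,   name: var_conscientiousness, center_mm: [0.0, -8.0, 32.0],    radius_mm: 8.0,
   baseline_coupling: 0.0,  trait_slope: {conscientiousness: 0.0075}, valence_class: variable}
- {seed_name: pcu_r, name: pos_pcu,               center_mm: [-4.0, -20.0, -20.0], radius_mm: 8.0,
   baseline_coupling: 0.5,  trait_slope: {},                         valence_class: invariant_pos}
- {seed_name: acc,   name: pos_acc_openness,      center_mm: [-6.0, 28.0, 24.0],   radius_mm: 6.0,
   baseline_coupling: 0.45, trait_slope: {openness: 0.004},          valence_class: invariant_pos}
- {seed_name: pcu_l, name: neg_pcu,               center_mm: [28.0, 4.0, -20.0],   radius_mm: 8.0,
   baseline_coupling: -0.45, trait_slope: {},                        valence_class: invariant_neg}
effect_halo_mm: 4.0       # signal is planted on the target dilated by this margin

noise:
  ar_coeff: 0.4                    # AR(1) coloring of the in-band observation noise
  bold_sigma: 20.0                 # fluctuation amplitude, arbitrary units
  baseline_intensity: 1000.0       # in-brain baseline before intensity normalization
  seed_noise_sigma: 0.1            # voxel noise inside seed regions
  drift_amplitude: 1.5             # low-frequency drift (removed by the band-pass)
  global_amplitude: 0.6            # global fluctuation (removed by nuisance regression)
  wm_amplitude: 0.8                # white-matter signal amplitude
  csf_amplitude: 0.8               # CSF signal amplitude
  motion_artifact_amplitude: 0.8   # motion-locked artifact amplitude
  motion_walk_mm: 0.05             # per-volume random-walk step of the motion params
  motion_spike_probability: 0.12   # fraction of later runs given a QC-failing excursion
  motion_spike_mm: 4.0             # excursion size (exceeds the 3 mm QC threshold)

preproc:
  despike: true
  despike_c1: 2.5           # robust-SD knee where outlier compression begins
  despike_c2: 4.0           # robust-SD bound of the saturating compression
  detrend_order: 2          # remove linear and quadratic trends
  f_lo_hz: 0.009            # temporal band-pass lower edge
  f_hi_hz: 0.1              # temporal band-pass upper edge
  smooth_fwhm_mm: 6.0       # Gaussian spatial smoothing kernel
  normalize_target: 10000.0 # grand-mean intensity normalization target
  wm_prob_threshold: 0.8    # 80% tissue-probability threshold for the WM mask
  csf_prob_threshold: 0.8   # 80% tissue-probability threshold for the CSF mask
  qc_threshold_mm: 3.0      # maximum head displacement for run retention (strict)

inference:
  cluster_z: 2.3            # cluster-forming threshold (Z > 2.3)
  alpha: 0.05               # corrected cluster-level alpha

confirm:
  n_permutations: 5000      # random pairings for the permutation null

rng_seed: 2026
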