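# Demo pipeline configuration: published search defaults with mild noise.
digestion:
  max_missed_cleavages: 5
  min_length: 6
  proline_rule: true
search:
  precursor_tol_ppm: 4.5
  fragment_tol_ppm: 20.0
  isotope_offset_max: 3
  max_charge: 7
  top_peaks_per_100da: 20
  mode: variable_mod
  allowed_mod_residues: DEKRSTCYNQHM
  max_var_mods_per_peptide: 1
validation:
  min_psm_score: 10.0
  max_abs_ppm: 3.0
  min_localization_prob: 0.9
  min_site_determining_ions: 2
  min_relative_intensity: 0.05
noise:
  fragment_dropout_prob: 0.05
  mz_jitter_ppm: 3.0
  intensity_cv: 0.2
  n_noise_peaks: 10
  noise_mz_range: [200.0, 2000.0]
species: ADPr
output_dir: adprscan_out
seed: 42
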