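# Synthetic spectrometer profiles.  Two instrument families with different
# native grids (100-3425 @ 1 cm^-1 and 100-4000 @ 3 cm^-1) plus a held-out
# external instrument for the dilution series and an independent-culture
# analyzer.  Offsets are small (neon-referenced, reasonably well-calibrated
# spectrometers agree to within ~0.5 cm^-1); effective band widths
# (resolution) differ by a few percent between instruments, and every
# instrument drifts a little
# from session to session (probe alignment, focus, temperature), modeled as
# per-batch offset/broadening jitter.  Channel noise is at a realistic
# shot-noise level relative to the water-dominated signal (band SNR of order
# 10^2, not 10^4).
site1_rxn2:
  grid_start: 100
  grid_stop: 3425
  grid_step: 1
  offset_cm1: -0.4
  broadening: 0.96
  noise_sd: 0.5
  baseline_degree: 4
  baseline_scale: 40
  scatter_sd: 0.08
  offset_jitter_sd: 0.03
  broadening_jitter_sd: 0.01
site2_rxn2:
  grid_start: 100
  grid_stop: 3425
  grid_step: 1
  offset_cm1: 0.5
  broadening: 1.0
  noise_sd: 0.55
  baseline_degree: 5
  baseline_scale: 60
  scatter_sd: 0.10
  offset_jitter_sd: 0.03
  broadening_jitter_sd: 0.01
site3_resspec:
  grid_start: 100
  grid_stop: 4000
  grid_step: 3
  offset_cm1: 0.35
  broadening: 1.12
  noise_sd: 0.5
  baseline_degree: 3
  baseline_scale: 50
  scatter_sd: 0.12
  offset_jitter_sd: 0.03
  broadening_jitter_sd: 0.01
site4_resspec:
  grid_start: 100
  grid_stop: 4000
  grid_step: 3
  offset_cm1: -0.3
  broadening: 1.07
  noise_sd: 0.5
  baseline_degree: 4
  baseline_scale: 45
  scatter_sd: 0.10
  offset_jitter_sd: 0.03
  broadening_jitter_sd: 0.01
tec5_external:
  grid_start: 150
  grid_stop: 3425
  grid_step: 1
  offset_cm1: 0.1
  broadening: 1.03
  noise_sd: 0.5
  baseline_degree: 4
  baseline_scale: 50
  scatter_sd: 0.10
  offset_jitter_sd: 0.03
  broadening_jitter_sd: 0.01
rxn2_independent:
  grid_start: 150
  grid_stop: 3425
  grid_step: 1
  offset_cm1: -0.02
  broadening: 1.0
  noise_sd: 0.45
  baseline_degree: 4
  baseline_scale: 45
  scatter_sd: 0.09
  offset_jitter_sd: 0.03
  broadening_jitter_sd: 0.01
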