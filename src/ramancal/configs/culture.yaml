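# Independent fed-batch culture on its own analyzer: daily-resolved samples,
# glucose fed to a low 4 g/L setpoint so its range (~2-4 g/L) is narrow
# compared with the pooled calibration range.
instrument: rxn2_independent
n_spectra: 21
site_id: external
batch_id: kth-fedbatch
kinetics:
  glucose_initial: 3.2
  glucose_setpoint: 4.0
  glucose_uptake_max: 0.12
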