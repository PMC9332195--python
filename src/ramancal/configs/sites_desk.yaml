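# Desk-scale corpus (~10% of the full spectrum counts, same batch structure,
# instruments and per-site operating ranges) for fast seeded experiments and
# tests.
scenario: desk
sites:
  - site_id: site1
    instrument: site1_rxn2
    n_batches: 6
    n_spectra: 31
    kinetics: {glucose_initial: 8.0, glucose_setpoint: 8.0}
  - site_id: site2
    instrument: site2_rxn2
    n_batches: 22
    n_spectra: 96
    kinetics: {glucose_initial: 12.0, glucose_setpoint: 12.0}
  - site_id: site3
    instrument: site3_resspec
    n_batches: 4
    n_spectra: 30
    kinetics: {glucose_initial: 16.0, glucose_setpoint: 16.0}
  - site_id: site4
    instrument: site4_resspec
    n_batches: 7
    n_spectra: 15
    kinetics: {glucose_initial: 10.0, glucose_setpoint: 10.0}
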