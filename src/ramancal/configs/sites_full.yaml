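# Full-scale calibration corpus: 305/958/295/148 spectra (1699 total) from
# 6/22/4/7 batches at four sites on two instrument families.  Glucose
# setpoints differ per site, so each single-site calibration covers only a
# slice of the pooled operating range — the pooled "generic" set owes much
# of its transferability to that range diversity.  Setpoints are arranged so
# the two instrument families see similar overall concentration
# distributions (the family signature carries no concentration information).
scenario: full
sites:
  - site_id: site1
    instrument: site1_rxn2
    n_batches: 6
    n_spectra: 305
    kinetics: {glucose_initial: 8.0, glucose_setpoint: 8.0}
  - site_id: site2
    instrument: site2_rxn2
    n_batches: 22
    n_spectra: 958
    kinetics: {glucose_initial: 12.0, glucose_setpoint: 12.0}
  - site_id: site3
    instrument: site3_resspec
    n_batches: 4
    n_spectra: 295
    kinetics: {glucose_initial: 16.0, glucose_setpoint: 16.0}
  - site_id: site4
    instrument: site4_resspec
    n_batches: 7
    n_spectra: 148
    kinetics: {glucose_initial: 10.0, glucose_setpoint: 10.0}
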