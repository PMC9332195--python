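# External-validation dilution series: one stock with a culture-like
# composition is diluted so that glucose takes the ten printed levels (g/L),
# each prepared in triplicate and measured on the held-out instrument.  The
# other analytes scale proportionally from their stock concentrations
# (glutamine/glutamate solubility caps them far below glucose).
levels: [100, 50, 40, 30, 20, 11, 9, 7, 5, 3]
replicates: 3
instrument: tec5_external
composition: {glucose: 100.0, lactate: 30.0, glutamine: 8.0, glutamate: 4.0}
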