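# Demo configuration for `recscreen run`: a miniature deletion-collection
# screen with known per-cell recombination rates (events/cell), including a
# wild-type-like strain, a few hyper-recombination mutants at rates taken
# from the validated patch-screen hit table, and a recombination-dead strain
# that only scores through the background channel.
strain_rates:
  WT: 1.14e-5
  TSA1: 1.23e-4
  RAD27: 9.39e-5
  RMI1: 7.50e-5
  SGS1: 3.75e-5
  NEUTRAL1: 1.1e-5
  NEUTRAL2: 1.2e-5
  DEAD: 0.0
universe: 4500
truth_rate_min: 3.0e-5
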