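# Example run configuration: palmitate feeding with the calibrated
# defaults, overriding one model parameter and the clamp level.
model:
  parameters:
    ki_acc: 8.5
protocol:
  fatty_acid: palmitate
  clamp_value_uM: 30.0
  t_step_s: 8000.0
solver:
  rtol: 1.0e-8
  atol: 1.0e-12
seed: 0
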