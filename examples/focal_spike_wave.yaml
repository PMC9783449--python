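# Default focal spike-wave scenario: one 40 nAm source, 2-minute run.
duration: 120.0
fs: 1200.0
seed: 1
n_channels: 64
conductor:
  center: [0.0, 0.0, 0.0]
  radius: 0.09
background:
  rms_t: 1.2e-13
  alpha_fraction: 0.35
  sensor_noise_rms_t: 2.5e-14
sources:
  - position: [0.02, 0.035, 0.055]
    kind: spike_wave
    rate: 0.2
    duration: 0.8
    amplitude_nam: 40.0
    waveform_policy: fixed_template
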