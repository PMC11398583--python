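# 3-layer channel-height profile (young-adult to day-1-adult devices).
# PLACEHOLDER layer heights/boundaries: true channel profiles are per-device
# calibration data; calibrate before quantitative volume use.
name: 3L
boundaries_um: [0.0, 1000.0, 2000.0, 3000.0]
heights_um: [50.0, 40.0, 30.0]
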