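# 4-layer channel-height profile (accommodates L4 larvae through adults).
# PLACEHOLDER layer heights/boundaries: true channel profiles are per-device
# calibration data; calibrate before quantitative volume use.
name: 4L
boundaries_um: [0.0, 750.0, 1500.0, 2250.0, 3000.0]
heights_um: [50.0, 40.0, 30.0, 22.0]
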