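# Reference SM-SegNet channel plan, solved by constrained enumeration
# (smsegnet.plan.solve_channel_plan) against the published trainable-parameter
# budget of 835,776 for the combined configuration.  Constraints: two fire
# modules per level sharing widths, expand widths doubling per encoder level
# with e1 == e3, decoder mirroring the encoder (shifted one level so every
# decoder block emits the channel count its unpooling indices were recorded
# with), bottleneck expand equal to the deepest encoder expand, and squeeze
# widths solved exactly with minimal total deviation from the SqueezeNet-style
# ratio squeeze = expand/2.
plan:
  encoder_expand: [20, 40, 80, 160]
  encoder_squeeze: [18, 21, 37, 81]
  bottleneck_expand: 160
  bottleneck_squeeze: 81
num_classes: 4
input_size: [128, 128, 1]
long_skips_enabled: true
combined_connections_enabled: true
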