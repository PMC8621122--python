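# Bone-embedded frame for the trapezium (distal segment of the thumb base
# in this workflow's convention).
name: trapezium
bone_label: 1
origin: trapezium_saddle_center
axis:
  from: trapezium_ulnar_tubercle
  to: trapezium_radial_tubercle
  name: i
plane:
  landmark: trapezium_distal_ridge
  name: j
signs: [1, 1, 1]
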