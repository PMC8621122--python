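# Bone-embedded frame for the first metacarpal (proximal segment of the
# thumb base in this workflow's convention).
name: first_metacarpal
bone_label: 2
origin: mc1_base_center
axis:
  from: mc1_base_center
  to: mc1_head_center
  name: j            # long axis of the metacarpal
plane:
  landmark: mc1_radial_tubercle
  name: i
signs: [1, 1, 1]
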