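# Frame for the distal bone of the synthetic two-bone joint phantom.
# With the default landmark recipe this frame coincides with the world
# axes at the reference posture.
name: phantom_distal
bone_label: 1
origin: dist_-x
axis:
  from: dist_-x
  to: dist_+x
  name: i
plane:
  landmark: dist_+y
  name: j
signs: [1, 1, 1]
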