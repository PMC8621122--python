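# Frame for the proximal bone of the synthetic two-bone joint phantom.
name: phantom_proximal
bone_label: 2
origin: prox_-x
axis:
  from: prox_-x
  to: prox_+x
  name: i
plane:
  landmark: prox_+y
  name: j
signs: [1, 1, 1]
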