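# Bone-embedded frame for the tibia (distal segment of the tibiofemoral
# joint).  See knee_femur.yaml for conventions.
name: tibia
bone_label: 1
origin: tibia_articular_surface_center     # center of the articular
                                           # surface of the tibia
axis:
  from: tibia_medial_plateau
  to: tibia_lateral_plateau
  name: k
plane:
  landmark: tibia_tuberosity
  name: j
signs: [1, 1, 1]
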