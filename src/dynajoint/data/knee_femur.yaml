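# Bone-embedded frame for the femur (proximal segment of the tibiofemoral
# joint), built from anatomical landmarks in the ISB spirit: the z axis
# points along the condylar line, x anteriorly, y along the shaft.
# The exact landmark-to-axis mapping is an editable modelling choice:
# adjust the names below to the landmarks present in your atlas.
name: femur
bone_label: 2
origin: femur_intercondylar_notch
axis:
  from: femur_medial_condyle
  to: femur_lateral_condyle
  name: k            # mediolateral axis
plane:
  landmark: femur_condyle_center_inferior   # most inferior point of the
                                            # center of the condyle
  name: j
signs: [1, 1, 1]
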