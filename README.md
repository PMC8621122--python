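# dynajoint

Automated estimation of in-vivo joint kinematics from dynamic (4D) CT.

Dynamic CT captures a moving joint as a time series of 3-D volumes, but
turning those images into clinically useful numbers — how much did the tibia
rotate relative to the femur, frame by frame? — normally requires manual
bone segmentation and manual anatomical landmarking on every dataset.
`dynajoint` automates that workflow for musculoskeletal researchers and
image-analysis engineers:

1. **Multi-atlas segmentation** of a reference frame: every annotated atlas
   is registered to the target with a three-stage scheme (rigid → affine →
   cubic B-spline free-form deformation; MSD, NCC or MI similarity, random
   sampling, multi-resolution), its labels are propagated, and the
   candidates are fused per voxel by majority vote (MV), globally ranked
   vote (GNCC) or locally weighted vote (LNCC, Gaussian kernel of size *k*,
   top *r* atlases per voxel).
2. **Landmark propagation**: atlas landmarks are mapped through the inverse
   registration transforms and a vote weighted by local normalized
   cross-correlation picks the winning position per landmark.
3. **Piecewise-rigid motion tracking**: each segmented bone, dilated by 3
   voxels to include its immediate vicinity, is tracked through the dynamic
   sequence by masked rigid registration (MSD metric), each frame
   warm-started from its temporal neighbour, giving per-bone transform
   series `T_bone,t`.
4. **Cardan-angle kinematics**: landmarks define bone-embedded reference
   frames (rows of `R` are the unit vectors **i**, **j**, **k** in scanner
   coordinates); the relative rotation
   `R_rel = R_distal · R_proximal⁻¹` is expressed against the reference
   posture and decomposed into intrinsic cardan angles (ZXY for the thumb
   base, ZYX for the knee).
5. **Validation tools**: Dice / false-positive / false-negative fractions,
   symmetric surface distances and Hausdorff distance, target registration
   error, leave-one-out cross-validation over an atlas population,
   Bland–Altman limits of agreement and ICC(2,k).

Because no patient data ship with the package, a **synthetic phantom
module** generates two-bone joint phantoms (cortical shell, trabecular
core, condyle-like lobes, CT-like noise), atlas populations under random
smooth diffeomorphic deformations, and dynamic sequences with exact
ground-truth transforms and landmarks — every stage of the pipeline is
testable against known truth.

## Worked example

Track a synthetic two-bone joint whose distal bone rotates 3°/frame about
the z axis, then recover the joint angles:

```python
import importlib.resources as resources
from dynajoint import track_bones, kinematics_pipeline, load_frame_definition
from dynajoint.phantom import (default_two_bone_spec, default_two_bone_motion,
                               generate_joint_phantom, generate_dynamic_sequence)

spec = default_two_bone_spec()                   # 64 mm two-bone joint phantom
atlas = generate_joint_phantom(spec, seed=7)     # image + labels + landmarks
motion = default_two_bone_motion(n_frames=6, rotation_per_frame_deg=3.0)
sequence, truth, _ = generate_dynamic_sequence(atlas, motion, seed=8)

tracked = track_bones(sequence, atlas.labels, dilation_radius=3, seed=9)

data = resources.files("dynajoint") / "data"
series = kinematics_pipeline(
    tracked, atlas.landmarks,
    load_frame_definition(str(data / "phantom_distal.yaml")),
    load_frame_definition(str(data / "phantom_proximal.yaml")),
    sequence="ZYX")
print(series.to_frame().round(3).to_string(index=False))
```

```
 frame  theta_z  theta_y  theta_x  valid
     0    0.000    0.000    0.000   True
     1    2.961   -0.016   -0.027   True
     2    6.066   -0.001   -0.019   True
     3    9.096    0.045   -0.031   True
     4   11.900   -0.038    0.100   True
     5   15.076   -0.008    0.042   True
```

The ground-truth `theta_z` is 0, 3, 6, …, 15°: the tracked angles recover
it to about a tenth of a degree, and the off-axis angles stay near zero.
The reference frame is (0, 0, 0) by construction; `valid` would flag frames
whose tracking fell back to the previous transform.

The same stages are available from the shell:

```bash
dynajoint simulate --out bundle --n-atlases 6 --n-frames 15 --seed 1
dynajoint segment  --target bundle/sequence/frame_000.mha \
                   --atlas-dir bundle/atlases --fusion lncc --k 5 --r 3 \
                   --seed 1 --out seg.mha
dynajoint track    --sequence-dir bundle/sequence --labels seg.mha \
                   --radius 3 --seed 1 --out motion/
dynajoint run      --config run.yaml        # the whole pipeline from YAML
```

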