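# facemark3d

Coarse-to-fine prediction of **32 facial soft-tissue landmarks** directly
from 3D surface point clouds.

Facial soft-tissue landmarks (endocanthion, pronasale, cheilion, gonion,
...) are the reference points of orthodontic and orthognathic measurement:
they define the median sagittal plane, quantify asymmetry, and anchor
pre-/post-operative comparison.  Manual annotation of 3D scans is slow and
inconsistent between operators; `facemark3d` automates it for researchers
working with stereophotogrammetric or other optical surface scans.

## Method

Given a scan `G` of K points (K varies between scans), the pipeline is:

1. **Normalize** the cloud into [-1, 1]^3 with an isotropic similarity,
   recording the scaling multiplier S (mm per normalized unit).
2. **Voxelize** onto an M^3 binary occupancy grid (cell width 2S/M mm),
   turning the unordered variable-size point set into a fixed-size tensor.
3. **Detect** six organ boxes (eyes, nose, lips, chin, right/left face)
   with a volumetric convolutional network: output `6 × 6` — per organ a
   vector `[x, y, z, xl, yl, zl]` of box center and per-axis half-extents.
   Training loss: `λ₁‖c − ĉ‖² + λ₂‖h − ĥ‖²` averaged over organs
   (λ₁ + λ₂ = 1).
4. **Crop** each organ with a margin, re-normalize and re-voxelize it, and
   **regress** its N landmarks (8/7/7/4/3/3) with a per-organ network
   (conv/pool/norm/sigmoid cycles + eight volumetric residual blocks),
   output dimension 3N.  Training loss on squared per-landmark distances
   d²: `λ₁·mean_i d_i² + λ₂·max_i d_i²`.
5. **Report** errors in mm via `L = S·√((x−x̂)² + (y−ŷ)² + (z−ẑ)²)`.

Because clinical scan datasets with 32-landmark annotations are not
publicly distributable, the package includes a parametric synthetic-face
generator (half-ellipsoid head + analytic nose/eye/mouth/chin features)
whose landmarks are exact by construction — see `docs/methods.md`.

## Worked example

```python
import facemark3d as fm
from facemark3d.pipeline import recovery_experiment

result = recovery_experiment(seed=1)   # 60 train / 20 test faces, M=32
print(f"detection IoU      {result['mean_box_iou']:.3f}")
print(f"mean error         {result['mean_error_mm']:.2f} "
      f"+/- {result['sd_error_mm']:.2f} mm")
print(f"box-center baseline {result['box_center_baseline_mm']:.2f} mm")
```

prints (a few CPU-minutes):

```
detection IoU      0.687
mean error         7.48 +/- 3.60 mm
box-center baseline 24.96 mm
```

Reading the numbers: the trained detector's boxes overlap the true organ
boxes at IoU ≈ 0.69 on held-out faces; the full coarse-to-fine pipeline
localizes landmarks to ~7 mm on average at this desk-scale operating point
(M = 32, where voxel quantization alone is up to 2S/M ≈ 6 mm per axis),
four times better than the naive baseline that answers every query with
the organ's box center.  The reference operating point is M = 200 with
600/500 training epochs (`RunConfig()` defaults); accuracy there is bounded
by grid precision < 1 mm but training is compute-heavy.

The same experiment is available from the shell:

```bash
facemark3d run workdir/ --config my_config.yaml   # simulate→train→evaluate
facemark3d simulate data/                         # synthetic dataset only
facemark3d infer-landmarks scan.ply workdir/ out.json
facemark3d evaluate predictions/ annotations/ report/
```

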