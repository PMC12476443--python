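# cathcalib

Catheter segmentation in X-ray angiograms and online self-calibration of a
biplane C-arm from the segmented catheter centerline.

## The problem

Interventional neuroradiology guides catheters and guidewires through
cerebral vessels under biplane fluoroscopy.  Reconstructing vessels or
instruments in 3D from the two views requires the projection geometry of
both C-arms; the gantry-recorded values (LAO/RAO and CAUD/CRAN angles,
source-to-image distance SID, source-to-object distance SOD) drift from the
true geometry through mechanical flex and table motion, which degrades any
triangulation built on them.  Dedicated calibration phantoms are impractical
mid-procedure — but the catheter itself, with its radio-opaque markers at a
known separation (typically 30 mm), is always in the field of view.

`cathcalib` implements that idea as two coupled components:

1. **Segmentation.**  A catheter crosses an image row or column as a sharp,
   narrow (≤ 5 px) negative deflection.  Per-line indicators — wavelet
   high-frequency energy `hf(t) = (Σ_j D_j(t))²` from a 3-level Daubechies-4
   decomposition, a squared smoothing-differentiator response `der(k)`, and
   a windowed quadratic-fit concavity score `cur(k) = θ₂(k)·θ₀(k)` — are
   combined per 5-px window with weights (0.8, 0.1, 0.1) and thresholded at
   0.1 to propose candidate regions.  Each candidate event is described by a
   64-dimensional feature vector (indicator statistics, signal moments,
   Frangi vesselness, DoG/LoG/bottom-hat responses, Hough-directional sums)
   and classified by a GentleBoost ensemble (480 stumps, learning rate
   0.006).  A vessel map built from the contrast sequence (DSA → Gaussian
   histogram-peak gating at b ≥ 0.65 → 1D 2-means → morphology) removes
   false positives; the surviving mask is skeletonized, spur-pruned, and
   gaps are bridged with Akima cubic Hermite interpolation to yield an
   ordered sub-pixel centerline.

2. **Self-calibration.**  Each view is a pinhole camera with
   K = [[SID/pu, s·SID/pv, u₀], [0, SID/pv, v₀], [0, 0, 1]] and the relative
   pose R = Rx(−β₂)Ry(α₂)(Rx(−β₁)Ry(α₁))⁻¹, T = T₂ − R·T₁.  100 samples of
   the view-1 centerline are matched to the view-2 centerline (200 samples)
   via epipolar lines (2.25 px gate, 1-px jump-consistency criterion), the
   matched pairs plus the exact marker pairs are triangulated, and bounded
   nonlinear least squares refines SID, skew, principal point, R and T until
   the backprojected reconstruction matches the measured centerlines, with
   the known 30 mm marker separation fixing the metric scale.

Clinical images cannot ship with the package, so a first-class synthetic
module generates biplane phantom acquisitions — 3D catheter splines with
markers, vessel trees, contrast-inflow sequences, distractor anatomy, noise
— with pixel-exact ground truth, and every claim in the test suite is made
against that generator.

## Worked example

```python
from cathcalib import synthetic as syn, interface, postprocess as post

# a synthetic biplane acquisition with ground truth
scene = syn.generate_scene(seed=0)
view1, view2, geometry = syn.render_views(scene)

# segment view 1 (oracle labels stand in for a trained model here)
oracle = lambda events: syn.label_events(events, view1.truth.catheter_mask)
seg = interface.run_segmentation([view1.image], oracle)
print(len(seg.centerlines[0]), "centerline points")

# calibrate from the truth centerlines after perturbing the gantry record
def centerline(v):
    return post.CatheterCenterline(
        points=v.truth.centerline_px, pixel_spacing=0.154,
        landmark_indices=tuple(scene.marker_indices), physical_length_mm=30.0)
intr, poses = syn.default_intrinsics(), syn.default_poses()
pi, pp = syn.perturb_geometry(
    intr, poses, syn.PerturbationMagnitudes(angle_deg=1.0), seed=3)
res = interface.run_calibration(centerline(view1), centerline(view2), pi, pp)
print(res.status, "before %.3f mm -> after %.5f mm"
      % (res.error_before_mm[0], res.error_after_mm[0]))
```

prints

```
469 centerline points
converged before 0.136 mm -> after 0.00000 mm
```

i.e. the non-learned stages recover the catheter centerline from the frame,
and the calibration reduces the mean 2D backprojection error of the
triangulated centerline from 0.136 mm (under the perturbed gantry record)
to the numerical floor.

A command-line interface wraps the same workflows:

```bash
cathcalib simulate --seed 0 --out sim/
cathcalib calibrate --view1 sim/view1_truth_centerline.csv \
    --view2 sim/view2_truth_centerline.csv --gantry sim/geometry.json \
    --out result.json
```

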