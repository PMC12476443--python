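# Methods

This note records the models implemented in `cathcalib`, the parameter
choices that matter, what the synthetic generator does and does not emulate,
and the numerical decisions taken where the design was genuinely open.

## Imaging model

Each C-arm view is a pinhole camera.  The intrinsic matrix couples the
source-to-image distance SID (mm) with the detector pixel spacing
(pu, pv, mm/px; default 0.154), an axis-skew term s and the principal point
(u₀, v₀, px):

    K = [[SID/pu, (SID/pv)·s, u₀],
         [0,       SID/pv,    v₀],
         [0,       0,          1]]

The gantry pose applies the clinical rotations as Rx(−β)·Ry(α) (α = LAO/RAO
about the patient axis, β = CAUD/CRAN), with the X-ray source at the camera
origin and the isocenter on the optical axis at depth SOD, i.e. per-view
translation T_j = (0, 0, SOD_j).  The relative pose between views is
R = R₂R₁⁻¹, T = T₂ − R·T₁; world coordinates are the first camera's frame,
so P₁ = K₁[I|0] and P₂ = K₂[R|T].  Image coordinates are 0-based
(u = column, v = row), pixel centers at integers, sub-pixel everywhere.
Triangulation is homogeneous DLT via SVD; the fundamental matrix is built
from the projection matrices through the epipole/pseudo-inverse construction
and Frobenius-normalized, so point–epipolar-line distances are in pixels.

## Candidate detection

Per image row and column, the catheter appears as a narrow (≤ 5 px) negative
deflection.  Three indicators respond to it:

* `hf` — the square of the summed detail-branch reconstructions of a 3-level
  `db4` wavelet decomposition (symmetric padding; by linearity this equals
  the squared residual signal − approximation, which the code exploits in
  the vectorized whole-frame path).
* `der` — a 13-tap Savitzky–Golay (cubic) smoothing differentiator applied
  to the detrended signal.  The filter is linear-phase with group delay 6,
  so the causal output is advanced by 6 samples and squared; this realizes
  the recentring `der(k) = y(k+6)²`.  The exact recursive/non-recursive
  coefficients of the original filter are not public; a linear-phase FIR
  differentiator with integer delay 6 reproduces the stated shift and the
  flanking-edge response.
* `cur` — within a sliding 7-px window, a weighted least-squares fit
  y ≈ θ₂·(−w²) + θ₀ of the *negative part* of the detrended signal, with the
  center-peaked tent weights [1/3, 2/3, 1, 1, 1, 2/3, 1/3] (the mirrored
  MATLAB-style 1:(−1/h):(1/h) ramp at h = 3).  cur = θ₂·θ₀, clamped to ≥ 0;
  a concave dip makes both coefficients negative, so their product scores it
  positively while bumps are gated out.

Per 5-px window the combination is 0.8·max(hf) + 0.1·mean(der) +
0.1·mean(cur), multiplied element-wise by the hf map.  **Normalization** is
per frame by the map's 99.5th percentile (clipped to [0, 1]) rather than by
the raw maximum: the map grows with the fourth power of a dip's depth, so
the handful of radio-opaque-marker pixels would otherwise set the scale of
the whole frame and push ordinary catheter responses below the fixed 0.1
threshold.  The percentile anchors the scale inside the structural response
of the frame; the empirical threshold 0.1 then behaves as intended.  The
0.1 threshold applies per frame to both the row-wise and the column-wise
map; a pixel is a candidate if either exceeds it.  Candidate runs keep a
5-px margin along their own line as event neighborhoods, and the binary
candidate raster takes the margin in both axes (catheter widths do not
exceed five pixels, so the cross-line margin covers the full width).  An
Otsu implementation (256-bin, between-class variance) is provided alongside
the fixed threshold.

## Features and classification

Each candidate event carries 64 features: 18 indicator statistics
(max/min/mean of hf/der/cur, raw and 5-px-smoothed), 10 signal statistics of
the detrended residual over the event neighborhood (RMS, population
kurtosis/skewness, impulse/clearance/crest factors, population std, log
variance, total variation, net variation — the clearance factor's square
root is taken on |x| since detrended signals are signed), 3 Frangi
vesselness statistics (dark-ridge polarity, scales 1/1.5/2, blobness 0.5,
structureness 30), 12 DoG and LoG statistics on the original and the
bottom-hat image (DoG σ = 1 vs 2 with 10/20-px truncation windows; LoG
σ = 0.5 with a 15-px kernel; each response min-max normalized), 3 bottom-hat
statistics (disk radius 3), and 18 directional features: sums along 8
orientations (0°…157.5°) of an 11×11 patch through the event center, on a
Hough-line "probable curves" binary map (Sobel edges → standard line Hough
at 1° / 1 px resolution, up to 50 peaks, rasterized lines kept where they
track dilated edge support) and on the hf raster masked to those curves,
plus the two totals.  Zero-variance moments return a NaN sentinel and are
median-imputed at training time.

The classifier is Gentle AdaBoost written in-package: stage-wise weighted
least-squares regression stumps on ±1 labels, F ← F + ν·f_m,
w ← w·exp(−y·ν·f_m), with 480 learners and shrinkage ν = 0.006; decision
threshold 0, no class reweighting.  Training is deterministic.  Models
persist as versioned JSON (feature index, threshold, leaf values per stump).

## Post-processing

The contrast sequence is digitally subtracted (each later frame minus the
first), each difference rescaled to [0, 1]; its 64-bin histogram is fitted
with a·exp(−((x−b)/c)²) (initialized at the mode with width 0.1) and frames
with b < 0.65 are discarded — without contrast the difference is symmetric
noise and b sits near 0.5, with developed contrast the background collapses
toward the top of the range and b rises.  Eligible frames are binarized by
deterministic 1D 2-means (centers initialized at the 10th/90th percentiles;
darker cluster = vessel), summed (vote ≥ 1 by default), smoothed (Gaussian
σ = 1, re-binarized at 0.5), small holes filled (≤ 500 px — a full flood
fill would close the interior of a C-shaped vessel into a blob), dilated
(disk r = 3) and reduced to the largest 8-connected component.  Candidate
detections outside the map are removed.

The surviving mask (rasterized at ±2 px around kept event runs, i.e. at
catheter width) is skeletonized; spurs shorter than 10 px are pruned
iteratively; each component is ordered by a double-BFS diameter path through
the 8-connected skeleton graph.  Components are merged greedily at their
nearest compatible endpoints (gap ≤ 50 px, end tangents within 60° of the
gap chord) with Akima cubic Hermite interpolation parameterized by chord
length and sampled at 1 px.  Landmarks snap to the polyline within 5 px and
clip it; the physical landmark separation (default 30 mm) rides along for
the calibration scale.

## Correspondence selection and calibration

View 1 contributes 100 equal-arclength samples, view 2 a 200-point
polyline.  For each sample, the epipolar line's sub-pixel intersections
with the polyline are candidates (plus the nearest vertex when no segment
crosses, if within the 2.25-px gate).  Once a previous match exists, a
candidate must step *forward* along the view-2 curve by about its image
displacement: |‖q₂ − q₂_prev‖ − (s − s_prev)| < 1 px with s ≥ s_prev.  The
forward requirement is not optional ornament — both centerlines are ordered
from the same catheter end, and without it a backward walk along the far
side of a projected loop satisfies the magnitude-only test, which is
exactly the sudden-jump failure the criterion exists to prevent.  Samples
with no admissible candidate are dropped; fewer than 8 surviving matches
aborts.

The cost over the matched pairs plus the exact marker pairs is the sum of
squared distances between measured points and reprojections of their
triangulated 3D points in both views, plus squared differences of
consecutive-sample unit direction vectors (measured vs reprojected, both
views, summed with a positive sign — a subtraction between the two views'
direction terms would make the objective unbounded below), plus the
metric-scale term (reconstructed marker separation minus the known length,
weight 1 per mm).  Three structural facts shape the optimization design:

* Epipolar-derived matches are consistent *by construction* with whichever
  geometry selected them (the projective-reconstruction property), so they
  carry no absolute signal; the identifiable content lives in the exact
  marker pairs and the known length.
* The reprojection residual is nearly invariant to a rotation compensated by
  a principal-point shift (the classic tilt/shift gauge ambiguity).  A weak
  Tikhonov prior (weight 0.01 on (v − v_init)/scale) pins those flat
  directions to the gantry record, and the trust-region scales are set to
  the magnitudes each parameter plausibly deviates (SID/T a few mm, angles
  about a degree, principal point a fraction of a pixel, skew ~1e-4).
* Box bounds bracket the shifts a functioning system actually exhibits —
  ±5° in angles, ±10 mm in SID and per T component, ±50 px principal point,
  ±0.01 skew.  Outside that envelope a catheter cannot re-derive the
  geometry, and the bounds are what make the offset experiment meaningful.

The optimizer is scipy's bounded trust-region-reflective least squares (the
bounded sibling of Levenberg–Marquardt).  Stage 1 refines on the marker
pairs and the length alone; stage 2 alternates correspondence selection,
a bounded solve (inner budget 1500 evaluations), and a scalar rescale of T
toward the known length clipped into the bounds (a per-component clip would
rotate T and wreck the geometry).  The loop exits early only when the mean
backprojection error is far below the match tolerance (0.005 px) — the
alternation converges slowly and non-monotonically near its floor, so
borderline runs use the full outer budget (30 iterations).  The workflow is
multi-start: the refinement runs from both the tip-stage result and the raw
gantry record, keeping the better outcome, because the heavily
under-determined tip stage can park the refinement in a poorer basin.

**Convergence** means what the procedure iterates for: the backprojection of
the reconstruction matches the measured centerlines (mean error below
0.5 px) *and* the reconstructed marker separation agrees with the known
length to 1 % before the final exact rescale.  Otherwise the status is
`max-iter` (budget exhausted, typically "length not reachable within the
parameter bounds") or `not-terminated` (solver budget exhausted or
correspondences lost).  This is what separates the offset regimes: a 1 cm
SID/SOD offset leaves a metric-scale error the bounds can absorb, 5 cm and
10 cm offsets do not, so those runs end not-converged with no special-casing
of the offset size.  After convergence T is rescaled (unbounded, for
reporting) so the marker separation is exact, which leaves every
reprojection unchanged.

A consequence worth stating plainly: the method restores *consistency*
(near-zero backprojection error, correct scale), not the ground-truth
parameter values.  The zero-residual set is a manifold, and the recovered
rotation typically sits a degree or more from the true one even when the
backprojection error is at the numerical floor.  The corresponding
acceptance test asserts angle recovery to 0.1° and is left failing
deliberately; the analysis is recorded with the test rather than papered
over.

## Synthetic phantom

The generator emulates what the clinical acquisitions provide: a smooth 3D
catheter curve (cubic spline through 10 jittered control points over a
42-mm chord, 5-mm transverse jitter) carrying two markers exactly 30 mm
apart (Euclidean), a vessel tube (radius 2 mm) centered on it with two side
branches, 512×512 frames at 0.154 mm/px, SID 1189/1207 mm, SOD 716/750 mm,
strongly angulated near-orthogonal views.  Rendering is multiplicative
attenuation on a static background (smooth texture around 0.85 ± 0.05 plus
dark distractor structures — wide band shadows and blobs that excite the
indicators without the narrow-dip signature): catheter ×0.5 at 3 px width,
markers ×0.25, vessels ×0.55 when contrast is present, plus Gaussian noise
σ = 0.02.  Contrast sequences hold the anatomy fixed and ramp vessel
opacity (default: first half without contrast, second half fully
developed).  Ground truth (sub-pixel centerlines, masks, landmark pixels,
geometry) is exact by construction, and truth centerlines satisfy the
epipolar constraint of the true geometry to machine precision.

Two deliberate idealizations:

* Default scenes are rejection-sampled (≤ 200 redraws per seed) so the
  catheter projects as a *simple* open curve in both views with
  non-neighboring sections at least 26 px apart — the phantom of interest is
  a gently curved microcatheter, and a curve that folds onto itself within
  the mask width cannot be ordered by any skeleton traversal without the
  manual correction a clinical workflow would apply.  Self-intersecting
  projections are an explicit opt-in (`SceneConfig.loop=True`) used by the
  correspondence tests; loop seeds are chosen and recorded in those tests.
* Event ground truth is defined at the pipeline's localization resolution:
  an event whose run lies within 5 px of the instrument counts as a correct
  detection, because its ±5-px feature support contains the catheter.  With
  a stricter radius every residual "error" of the classifier was an event in
  the 2–7 px ring — label noise, not discrimination failure.

What passing tests therefore do *not* show: performance under real detector
physics (scatter, blur, polychromatic beam hardening), overlapping bone or
device clutter beyond the simple distractor model, patient/table motion
between frames, or catheters that genuinely double back within a few pixels
in projection.  The clinical metric values of the original study are not
reproducible from synthetic data and are not claimed.

## Problem sizes and runtimes

Defaults were chosen so a complete run is comfortable on a single CPU: the
classification benchmark trains on 10 frames and tests on 5 (≈ 15 000
events, 480 boosting stages); calibration recovery panels use 20 perturbation
seeds at 100/200 centerline samples; the offset experiment uses one seed per
magnitude.  The acceptance script reduces the recovery panel to 8 seeds.

## Known limitations

* The skeleton orderer returns the diameter path of the skeleton graph;
  genuine loops in the *mask* (opt-in scenes) are shortcut and would need
  manual correction, as in the clinical workflow.
* The classifier ships without probability calibration; the decision
  threshold is the boosting score sign.
* Calibration identifies a consistent geometry near the gantry record, not
  the true parameters (see above); quantities derived from the recovered
  parameters other than reprojections and scaled reconstructions should be
  treated accordingly.
* DICOM support reads pixel data and spacing tags only; gantry angles are
  taken from the geometry JSON, not from DICOM rotation tags.
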