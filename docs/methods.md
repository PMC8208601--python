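# Methods

This note documents the models and procedures implemented in `sct4d`, the
assumptions behind them, the parameters that matter, and the design choices
made where the design was genuinely open.

## Coordinate and field conventions

All volumes live on axis-aligned voxel grids indexed `(x, y, z)`; physical
coordinates are millimetres from the origin (centre of voxel `(0,0,0)`).
Displacement fields are **pull-back** maps: warping an image `A` with field
`u` produces `out(x) = A(x + u(x))`. This matches how standard resampling
routines consume fields and makes composition explicit:
`compose(u1, u2)(x) = u2(x) + u1(x + u2(x))` equals "warp with `u1`, then
`u2`". Whether the original workflow's registration tool emitted pull-back
or push-forward fields is not documented anywhere we could verify; the
convention here is a documented choice, not an inference. Out-of-domain
samples are filled per modality (−1000 HU for CT-like volumes, 0
otherwise).

Field inversion uses damped fixed-point iteration
`v ← v + ω(−u(x + v) − v)` with ω = 0.5 and tolerance 0.01 mm. The damping
widens the convergence region to fields with local gradients approaching
the contraction limit, which estimated (as opposed to analytic) fields
routinely have near the volume boundary.

## Similarity

NMI is `(H(a)+H(b))/H(a,b)` from a joint histogram with equal-width bins
over each image's observed range, 64 bins by default (no binning scheme is
prescribed anywhere authoritative). Two identical constant images score
2.0 by definition; a single constant image has zero entropy and the score
is undefined (raised as an error rather than guessed).

## Registration backend

The bundled backend is a symmetric-force demons solver with Gaussian
elastic regularization on a 3-level pyramid (field-smoothing sigmas
6/4/2.5 mm, 40/25/12 iterations). It exists so the pipeline runs with no
external binary; no equivalence with any production registration package
is claimed, and precomputed fields can be injected instead
(`load_external_field`). Three robustness measures matter in practice:

- **update gating** — demons forces are zeroed where the fixed image has
  no structure (gradient magnitude below 5% of its 99th percentile);
  otherwise noise-only regions random-walk at the step bound;
- **finest-spacing step bound** — the per-iteration step is capped at
  0.8× the finest-level voxel size at *every* pyramid level, because a
  coarse level otherwise locks aliasing artefacts in at its own voxel
  scale where fine levels (gated, low gradient) cannot undo them;
- **support extrapolation** — after registration the field in gated
  regions is replaced by the nearest supported displacement, decayed with
  distance (e-folding 15 mm) and smoothed, so the field stays continuous
  and invertible, regions far from any structure relax to zero, and
  forward/backward registrations remain approximately inverse.

Cross-contrast pairs (different modality tags, e.g. Dixon in-phase to
fat-suppressed T1w) are first remapped into a mutually predictable
representation via conditional means of the joint histogram
(`m' = E[f | m]`, `f' = E[m' | f]`): detail visible in only one contrast
flattens on both sides instead of driving spurious SSD forces. This is a
cheap stand-in for a true information-theoretic metric and is the weakest
link of the bundled backend; tests hold it to feature-level (centroid)
accuracy, not voxelwise field accuracy.

Divergence is detected per pyramid level against that level's own starting
similarity (MSE is not comparable across resolutions); two consecutive
worsening levels raise an error with the history attached.

## Motion model

The reference phase `j` maximises NMI between the T1w phases and the Dixon
in-phase volume (exhale-gated, or free-breathing with four averages, which
lands near exhalation; both are treated identically). Inter-phase fields
are chained — adjacent phases registered stepping outward from `j`, steps
composed — so each registration bridges only a small respiratory step. The
MidP field is the weighted arithmetic mean of the forward fields
DVF(Tj→Tn) with uniform weights: the phases are equal-width sorted bins of
the cycle, so each represents the same fraction of time. Whether forward
or inverse fields should be averaged is not settled; forward averaging is
the documented choice. Dixon volumes reach MidP by one warp with
`compose(DVF(Dj→Tj), DVF(Tj→MidP))`; 4D resynthesis warps the MidP volume
with `compose(inv(DVF(Tj→MidP)), DVF(Tj→Tn))`, carrying the inversion
residual as a warning when it exceeds tolerance.

## Tissue segmentation (Dixon)

The combined mask `M` (background + lungs) thresholds the summed fat+water
image at its mean over all voxels (zeros included — the literal reading);
zero padding guarantees the exterior is one border-connected component,
the largest component of `M` is the background `B`, and `L = M − B`. Fat
is the largest connected component of the body-masked fat image above its
mean non-zero intensity; water is the rest of the body. Component analysis
uses 6-connectivity. No morphological cleanup is applied to the water mask
(none is prescribed); voxels in neither fat nor water become soft tissue
at build time.

## Spine atlas

Spine extraction from CT: threshold 125–1500 HU, keep the largest
connected component (reading "first component = rib cage" as largest by
voxel count; label-index order is an implementation artefact), dilate and
close with an ellipsoid structuring element of radii (1, 1, 2) voxels
(radii, not diameters — the ambiguity is resolved here), crop to a
rectangular ROI propagated over all axial slices, and flood-fill holes
slice-wise (the vertebral canal is a through-hole in 3D and only closes
per slice). The ROI is a config parameter defaulting to a box on the
posterior third of the axial midline; the phantom ships ground-truth ROIs.

Atlas ranking registers every atlas fat image to the incoming fat image,
warps its spine mask along, and scores NMI between incoming and registered
fat restricted to the warped spine mask ("segmented" is read as
spine-masked). Fusion is plain intensity override inside the mask.

## Lung model

1. **Bias correction** divides the T1w volume by a 3×3×3-median-filtered,
   guided-filtered scanner-reconstructed T1w volume. The filter estimates
   the smooth receive-coil profile, so its defaults are deliberately
   coarse: radius 8 voxels, ε = (0.4 × range)² — close to a box blur. An
   edge-preserving setting (small ε) keeps tissue detail in the divisor
   and cancels the very intensity signal the lung fit needs; on the
   phantom the lung intensity–HU correlation drops from 0.85 to 0.22 with
   radius 4 / ε = (0.1 × range)², versus 0.75 with the adopted defaults.
2. **Water normalisation** rescales so the mean over the water mask equals
   a common reference (the first training subject's water mean), making
   subjects comparable.
3. **Sampling**: 10⁷ non-zero lung points (without replacement when the
   lung holds that many voxels, with replacement otherwise — the phantom
   lung is far smaller than a patient lung), re-balanced over 20
   equal-width intensity bins at exactly 5000 random pairs per adequately
   populated bin; sparse bins contribute everything they have, with a
   warning.
4. **Fit**: ordinary least squares on the raw quintic Vandermonde design.
   On narrow intensity ranges the monomial basis is strongly collinear, so
   individual coefficients are not interpretable — predictions are — and
   the training metadata records the residual RMS.
5. **Application** replaces lung voxels by the polynomial of the
   bias-corrected, water-normalised MidP T1w intensity, inputs clamped to
   the trained range and predictions clamped to [−1000, 100] HU.
6. **Rescaling** (emphysema workflow) multiplies lung HU by
   `target/median`; multiplicative scaling is the only linear map that
   keeps −1000-anchored air moving consistently toward more negative HU,
   preserves voxel ordering, and lands the median exactly (default target
   −865 HU).

Leave-one-out training pools lung voxel pairs across the remaining atlas
subjects before the binned sampling; each subject's own MidP T1w serves as
its scanner-reconstructed reference for bias correction.

## Builders

`BulkHUTable` carries the four bulk values (fat −110, soft tissue 70, air
−1000, lung −767 HU) with the invariant `air ≤ lung < fat < soft`. The
three methods nest exactly: sCT_DS differs from sCT_D only on the warped
spine-mask support, sCT_DSL additionally only on the lung mask. Every
file-based output gets a sidecar JSON with the configuration hash, seed
and selection details.

## Evaluation

Dose-volume metrics use plain voxel counting on sorted in-mask doses
(voxel volume = product of spacings): `D_x` is the k-th largest in-mask
dose with `k = ceil(requested volume / voxel volume)`; near-max dose is
`D` at an absolute volume (0.5 cm³ default); `V_x` is the in-mask fraction
at or above the threshold; the conformity index is PTV volume over total
isodose volume. Treatment-planning systems interpolate sub-voxel DVHs in
proprietary ways; voxel counting is the only choice an enumeration oracle
can verify exactly, and all metrics are tested against such oracles.
Paired comparisons use the Wilcoxon signed-rank test (two-sided, zero
differences dropped, exact null for n ≤ 25 when tie-free, normal
approximation with continuity correction otherwise; α = 0.05).

## Digital thorax phantom

The phantom is the test substrate: an elliptical body (semi-axes
100 × 75 mm) with a fat shell, two ellipsoidal lungs, a spine cylinder
with vertebral canal and fatty-marrow signal, detached rib arcs, and a
10 mm spherical tumour in the right lung, on an 80 × 80 × 44 grid at
3 × 3 × 4 mm (defaults). Key constructions:

- **Motion** is affine in the cranio-caudal coordinate,
  `z → z + A_n (1 + βz)` with `A_n = A sin²(πn/N)` (A = 12 mm SI, 3 mm AP,
  N = 20), full amplitude at the diaphragm decaying to 15% at the apex.
  Affine maps are exactly invertible in closed form, so per-phase
  ground-truth fields and their inverses are analytic; phase 0 is exhale
  and the time-averaged (MidP) displacement is exactly A/2 at the
  diaphragm.
- **Lung density** is a known quintic of the smooth T1w lung texture
  (cosine mixture, 60 mm scale); the constant term is anchored so the
  *rendered* (imaging-blurred) exhale lung median equals −808 HU — the
  blur mixes boundary voxels with brighter soft tissue, so a crisp-field
  calibration would land visibly high. The emphysema variant adds air
  pockets and anchors the median at −865 HU instead. A misspecified
  piecewise-linear variant is included as a stress fixture.
- **MR signal** is tissue intensity × a smooth multiplicative bias field
  (static in the scanner frame, ±15% by default) plus Gaussian noise on
  the magnitude (valid above SNR 20, where Rician noise is
  near-Gaussian), then blurred by 0.5 voxel of imaging PSF. Rib-band
  axial edges are rendered with analytic partial volume and offset off
  the voxel lattice; structure edges aligned with voxel centres would
  otherwise jump whole voxels under sub-voxel motion.
- **Spine ground truth** includes a thin (1.7 in-plane voxels)
  peri-cortical margin below the bone threshold; the extraction recipe's
  dilation step is exactly what recovers it.
- **Atlas cohorts** jitter body/lung/spine sizes and positions per
  subject, draw each subject's lung median uniformly from
  [−830, −780] HU, and perturb the quintic coefficients by ~3%, so
  leave-one-out cross-validation is non-trivial.

What the phantom does **not** emulate: realistic MR physics (sequence
contrast, T1/T2, susceptibility), irregular breathing, hysteresis,
sliding-organ discontinuities at the pleura, airway trees, and
XCAT-grade anatomy. Passing tests therefore demonstrate the correctness
and internal consistency of the processing chain under smooth, periodic,
well-posed conditions — not clinical-grade accuracy on patients.

## Problem sizes and numerical choices

Default test and acceptance runs use the 80 × 80 × 44 phantom with 20
phases and 5-subject atlases — large enough for every recipe (connected
components, binned sampling, chained registration) to operate in its
intended regime while the whole suite stays desk-scale. Degenerate inputs
are handled explicitly: constant images (NMI, segmentation thresholds),
empty masks (errors or warnings as contracts state), under-populated
sampler bins (all points + warning), non-convergent inversions (warning +
reported residual), ties in phase selection (lowest index wins).

## Known limitations

- The bundled demons backend under-recovers large chained deformations in
  regions whose motion is unobservable from image structure (flat tissue,
  boundaries parallel to the motion); feature-level accuracy (tumour
  centroids: MidP within 0.5 voxel, resynthesis within 1 voxel) is what
  the tests guarantee.
- Cross-contrast registration via conditional remapping leaves ~1.5 mm
  residual misplacement near class-ambiguous structures on the phantom; a
  production workflow should inject fields from a dedicated registration
  package.
- Coefficients of the raw quintic are ill-conditioned on narrow intensity
  ranges; only predictions are stable across seeds.
- Dose grids are inputs; no dose calculation, plan optimisation or margin
  derivation is provided.
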