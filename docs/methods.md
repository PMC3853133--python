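# Methods

`limbcast` analyses the *shape-capture consistency* of below-knee
(transtibial) residual-limb casts. The clinical question: when a prosthetist
casts the same residual limb twice with the same method — moulded by hand
("hands-on", the patellar-tendon-bearing tradition) or by a uniform-pressure
air bladder over a liner ("hands-off", the ICECast/hydrostatic tradition) —
how repeatable are the resulting limb shape and volume, and are the
differences large enough to matter for socket fit?

## Analysis pipeline

Each subject contributes four volumetric scans (2 casting methods × 2
repetitions). The pipeline mirrors the measurement protocol such studies
use:

1. **Isotropic resampling.** Scans are resampled to a 0.6 mm isotropic grid
   (linear for greyscale, nearest for masks); all downstream slice
   arithmetic assumes this spacing.
2. **Segmentation.** The limb (soft tissue ∪ bone) and the tibia are
   thresholded at class-midpoint levels, reduced to the largest 6-connected
   component, and 3-D hole-filled so a dark marrow cavity cannot perforate
   the bone mask. The thresholds sit midway between the soft-tissue mean and
   the mean of the class adjacent to the skin (the stockinet gap when
   present), which places the recovered surface at the half-filled
   partial-volume level.
3. **Tibia-anchored frame.** One of the four scans is selected at random as
   the reference. Its tibia is rotated so the transverse slices are parallel
   to the proximal bone surface: the bone's long axis is first estimated by
   PCA, the upper-envelope voxels within 2.5 mm of the proximal end
   *measured along that axis* are taken as plateau candidates (this keeps
   the down-sloping crest of a tilted shaft out of the selection), and a
   least-squares plane is fitted with a shrinking residual trim
   (2.5s → 0.8s, s = voxel size) that discards the intercondylar tubercle
   bumps.
4. **Registration.** The remaining scans are rigidly registered to the
   aligned reference by maximising normalised mutual information,
   NMI = (H(A)+H(B))/H(A,B), over a joint intensity histogram. The
   similarity is evaluated over a dilated tibia neighbourhood (default 6 mm)
   so soft-tissue differences between casts do not drive the bone-anchored
   fit. Optimisation is derivative-free (Powell) over a 3-level
   multi-resolution pyramid (downsampling 4/2/1, Gaussian pre-smoothing
   σ = factor/2), with a centre-of-moments translation initialisation.
   Registered masks are obtained by transforming the *greyscale* with linear
   interpolation and re-segmenting — the partial-volume ramp carries the
   surface at sub-voxel accuracy, whereas resampling a binary mask directly
   has a ~half-voxel boundary error that would dominate small shape
   differences.
5. **Standardisation.** All slices strictly above the 30th slice proximal to
   the tibial plateau are removed, giving every scan of a subject the same
   anatomical length. The plateau slice is the most proximal slice holding
   at least k = 5 bone voxels (a stray-voxel guard).
6. **Regional partition.** A sagittal plane through the two intercondylar
   tubercle landmarks and an orthogonal coronal plane through the plateau
   midpoint split the limb into anterolateral / anteromedial /
   posterolateral / posteromedial quadrants; two transverse cuts at 1/3 and
   2/3 of the subject's averaged standardised length (measured in mm from
   the distal tip) give distal / middle / proximal bands. Ties (a voxel
   exactly on a plane) go to the lateral / anterior / proximal side.
7. **Morphometrics.** Per scan: volume (voxel count × 0.216 mm³), regional
   volumes, length (slices containing limb × 0.6 mm), per-slice
   cross-sectional area (CSSA) and circularity. Per pair: the absolute shape
   difference — the volume of the symmetric difference (XOR) of the two
   registered, standardised masks — overall and per region, plus a
   common/only-A/only-B label volume for colour-coded difference images.
8. **Statistics.** Per metric and method: intra-cast mean difference and SD,
   ICC(2,1), CoV (100·SD/mean), a Shapiro–Wilk-gated paired comparison
   (paired t when the differences pass normality at α = 0.05, Wilcoxon
   signed-rank otherwise), and Bland–Altman bias with 1.96·SD limits of
   agreement. For CSSA/circularity, three slices are drawn at random (seeded,
   shared across the subject's four scans) in each longitudinal band.

### Circularity

Circularity is reported as P²/(4πA) so a perfect circle scores 1, with the
perimeter measured as the length of the marching-squares 0.5-level contour of
the largest in-slice region after a 5-vertex periodic moving-average — raw
marching-squares contours of binary data overestimate smooth perimeters by
up to ~10 % (staircase), while the smoothed polygon is within 1 % for a disc
and within 1 % of the continuous-limit value for a 200-pixel square. The
literal P²/A ratio and a Crofton pixel-based perimeter are exposed as
options. Under this convention realistic non-circular limb sections produce
values in the ≈1.1–1.4 range reported for residual limbs. Empty slices give
NaN, not zero; using only the largest region keeps stray distal-tip voxels
from exploding the ratio.

### The one-sock clinical criterion

A volume change equal to one prosthetic sock (measured by water displacement:
(1765.1−1635.2)/1635.2 = 7.94 %) is treated as the threshold of a clinically
meaningful fit change. Two tests are run: (a) (1 − 0.0794)·repetition-1
volumes against repetition-2 volumes with a paired test — a significant
difference means the intra-cast change is *smaller* than one sock (this
inference direction is unconventional but is the procedure as defined; the
package additionally reports an explicit verdict label); (b) per-subject
intra-cast shape difference against 7.94 % of the subject's four-scan mean
volume — significantly below gives `below_sock`, otherwise
`at_or_above_sock`.

## Synthetic phantom

No scan data are distributable, so the package ships a parametric phantom
with exact ground truth:

- **Soft tissue:** a tapered solid with superellipse cross-section
  (exponent 2.5, ML/AP aspect 0.52 → analytic circularity ≈ 1.17, inside the
  reported 1.16–1.34 band), proximal/distal AP semi-axes 18/10 mm, length
  46 mm, capped distally by a scaled hemisphere (loose distal soft tissue).
- **Bone:** a rigid tibia with an AP-elongated elliptical section (ML/AP
  0.75) tapering from a flared 15 mm-wide plateau to a 8 mm-wide distal end,
  flat plateau with two small tubercle bumps (1 mm radius, 1.8 mm tall)
  emitted as landmarks. The non-circular section matters: a circular shaft
  would leave rotation about the limb axis unobservable to bone-anchored
  registration, which no real tibia does.
- **Wrapping:** a 3 mm low-intensity stockinet gap and a 4 mm cast shell.
- **Rendering:** voxel intensities are composed from approximate
  partial-volume coverage fractions (linear ramp of the signed distance over
  one voxel), exactly as needed for threshold segmentation to recover the
  analytic surface at the 0.5-coverage level; a piecewise-constant mode
  exists for tests that require bit-exact class maps. Masks are produced by
  evaluating the analytic geometry at inverse-posed voxel centres — posed
  ground truth is exact, never resampled. Noise is additive Gaussian
  (segmentation robustness, not MR physics, is under test) and class means
  are kept ≥ 5σ apart.
- **Repeat-scan studies:** per subject, one geometry (radius and length
  scale factors drawn per subject: SD 12 % and 5 %, clipped) scanned four
  times; each scan gets a rigid pose jitter (uniform ±2°, ±3 mm — scanner
  repositioning is not well characterised, so this is a modelling choice,
  not a claim) and per-method surface deformations: compact-support radial
  Gaussian bumps (3 per scan by default) whose amplitude distribution is the
  method effect. Defaults make hands-on casting larger and more variable
  (mean |amplitude| 2.0 vs 1.0 mm, plus a +0.15 mm radial offset), matching
  the qualitative finding that manual moulding is less repeatable.

### Problem sizes

The phantom is a scaled-down residuum (~15,000 mm³ vs ~10⁶ mm³ for a real
limb) on a 96³ grid at 0.6 mm — the package's chosen working size, at which
a full 20-subject study runs in a few minutes. Some generator-level tests use
64³ at 0.9 mm. Consequences worth knowing: the XOR shape-difference floor
from voxelisation and interpolation is ≈1 % of limb volume here (it scales
with surface/volume ratio; for full-size limbs it is comparable to the ~1 %
registration error reported for bone-anchored CT registration), and the
standardisation crop retains 18 mm above the plateau rather than the full
proximal third of a real residuum.

### What the phantom does not emulate

MR pulse-sequence physics (bias fields, chemical shift, Rician noise),
muscle/fat contrast within soft tissue, non-rigid bone–soft-tissue motion,
and operator-in-the-loop segmentation. Passing tests therefore demonstrate
the *measurement chain* — registration, standardisation, morphometry,
statistics — under known ground truth, not scanner-specific robustness.

## Numerical choices

- Registration histogram: 32 bins during optimisation (a plain 2-D histogram
  of linearly interpolated samples stays densely populated and keeps the NMI
  surface smooth under 5 % noise; 64 bins left it too sparse and cost a
  recovery case). The `nmi()` similarity itself defaults to 64 bins, where
  sample counts are not a concern. Background excluded as the *intersection*
  of zeros — conditioning on "either non-zero" would manufacture dependence
  between independent images.
- Powell: ≤200 iterations/level, xtol 3·10⁻³·level-factor, ftol 10⁻⁵ on NMI;
  ≤120k histogram samples per level on a strided lattice.
- Mask resampling: linear interpolation of the indicator re-thresholded at
  0.5 (binary in, binary out, ~0.2-voxel boundary error); classical nearest
  neighbour available by option.
- ICC: ICC(2,1) — two-way random effects, absolute agreement, single
  measure — the standard test-retest form; ICC(3,1) is a config option.
  Undefined (NaN) when there is no variance to apportion.
- Degenerate inputs: all-zero paired differences report p = 1 with a
  degeneracy flag; constant images give NMI's lower bound 1 with a warning;
  CoV warns when |mean| < SD/10; empty bands in slice sampling draw all
  available slices and warn.
- No multiple-testing correction is applied, matching the table semantics
  this reproduces; a Holm option would be a one-line addition but is
  deliberately not default.

## Known limitations

- Rigid registration only; whether a bladder cast deforms the bone-soft
  tissue relation non-rigidly is out of scope (and the anchor is bone).
- The plateau plane fit needs ≥50 surface voxels and a plateau a few voxels
  wide; at 2° tilts the binary upper envelope is terrace-limited and the
  recovered tilt can be off by ~2° (all four scans of a subject share the
  frame, so metrics are consistent; at the 7–10° tilts the alignment step
  exists for, accuracy is ≈0.3°).
- Tubercle landmarks are ground-truth inputs (sidecar JSON for real data);
  no image-based landmark detection is attempted.
- `sock_volume_pct(1765.1, 1635.2)` = 7.94398 %, which truncates to the
  conventional printed 7.943 %.
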