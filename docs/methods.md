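# Methods

## Measurement model

The contact metric is defined entirely on the voxel grid of the segmented
volume. For a label volume with classes background/marrow, bone, implant and
excluded, the implant surface is the set of axis-aligned unit faces between
an implant voxel and a voxel of any other class (6-neighbourhood), with no
smoothing, decimation or sub-voxel interpolation. Keeping the surface
voxel-conserving makes the measured areas an exact function of the
segmentation — and makes the systematic staircase (aliasing) overestimation
of curved areas explicit: the lateral voxel-face area of a digitized
cylinder converges to 4/π ≈ 1.273 of the analytic lateral area. The
headline metric

    pVA = 100 · eBIC / pBIC

is a ratio of two areas measured on the same voxelization, so this factor
cancels; empirically pVA drifts well under 1 percentage point between
analysis voxel sizes s and s/2 while each area individually changes by the
aliasing factor.

Conventions:

- Faces use 6-connectivity (forced by face geometry); island analysis of
  bone uses 26-connectivity. Voxel indices are 0-based, boxes half-open; a
  face sits between voxel i and i+1 along its axis.
- pBIC counts shell faces against bone *and* against background/marrow — any
  shell face "could" have bone contact. Faces against `excluded` voxels are
  tallied separately and removed from pBIC, which is exactly the correction
  required when part of the shell is cropped away; faces on the volume
  border are ignored.
- End caps: the flat ends of the implant are not scored. Cap faces are the
  ±z-oriented faces at the implant's extreme z slices (±1 slice tolerance).
  The extremes are taken on the implant's *main body*: extreme slices whose
  cross-section holds less than 0.4 of the next inward slice are treated as
  cap roughness — scattered 1–2 slice layers that blur and noise attach to
  the flat caps after segmentation — and all their faces are dropped.
  Without this, cap-roughness faces masquerade as lateral shell and can
  inflate pVA by >10 pp at fine resolutions. The 0.4 ratio separates the
  two regimes cleanly: a genuine convex body never halves its cross-section
  per slice except at a single-voxel pole (digitized-sphere ratios stay
  ≥ 0.49), while measured roughness layers sit near 0.3.

## Processing chain

1. **Box resample** (2×2×2 block means): halves resolution, reduces data
   eightfold, and suppresses voxel noise by √8. It stays on by default: the
   subsequent unsharp mask has gain 1.5 and amplifies noise ~2.5×, which at
   realistic noise levels would otherwise push a fifth of the bone voxels
   across the background threshold.
2. **Unsharp mask**, applied per x-y slice: out = in + g·(in − lowpass), a
   5×5 uniform lowpass with edge replication. The gain convention is
   g = sharpness/(1 − sharpness) (sharpness 0.6 → gain 1.5); the vendor
   formula behind the "sharpness" naming is unpublished, so the plain
   g = sharpness variant is available via a flag. Output is clipped to the
   input range so edge overshoot cannot leave the grey scale. "5×-kernel"
   is read as 5×5 (not radius 5) — the milder of the two readings.
3. **Thresholds**: two global thresholds maximizing three-class
   between-class variance on a 256-bin histogram (multi-level Otsu).
   Reported thresholds are snapped to the midpoint between the two
   populations they separate, so the tie convention (a voxel exactly at a
   threshold goes to the lower class) can never flip an entire grey mode.
4. **Interface cleanup**: binary opening (ball radius 1) of the bone mask,
   restricted to a 3-voxel collar around the implant — this removes the thin
   spurious "bone" shell that the blurred metal edge and the halo produce in
   marrow gaps — followed by removal of bone islands under 27 voxels
   (26-connectivity). Implant voxels are never modified. These replace the
   interactive slice editing of a workstation workflow; the radius, collar
   and island cutoff are parameters because no published values exist.
5. **Outside-bone exclusion**: non-implant voxels above a cropping plane are
   relabelled `excluded`. In `auto` mode the plane is perpendicular to the
   implant axis at the lowest slice above which the implant perimeter's bone
   coverage stays below 50%. Coverage is measured on an annulus (width 4
   voxels) just outside the in-slice implant mask, after dilating the bone
   mask by 4 voxels; the dilation bridges marrow gaps and trabecular spacing
   (embedded slices score ≈1, emerged slices ≈0), making the 50% threshold
   robust to trabecular geometry. Air and marrow share the background
   label, so coverage is necessarily bone-based.

## Virtual 2D histomorphometry

A single-pixel longitudinal section through the implant axis (in-plane
centroid of the implant label) is resampled at a chosen angle with
nearest-neighbour labels; opposite angles give exact mirror images. The
implant profile's outer contour is traced (Moore neighbour tracing) and
measured with the Freeman chain-code convention: axial steps 1 pixel,
diagonal steps √2. The topmost/bottommost contour rows (the profile's end
caps) and contour pixels 8-adjacent to `excluded` pixels are dropped,
mirroring the 3D shell and exclusion semantics; both sides of the profile
are measured. BIC2D = 100 × (bone-adjacent contour length)/(total contour
length). An optional supersampling factor emulates histomorphometry's finer
pixel size. On prismatic contact geometry the angle-average of BIC2D
approaches pVA (observed within ~2 pp on sector phantoms); single sections
scatter widely, which is the point of the sweep diagnostic.

## Phantoms

The generator emulates a reconstructed µCT volume of a conical titanium
implant (defaults: 3 mm max diameter, 3 mm length, 10° taper, axis on z,
widest end up) embedded in a bone block, with a border of air around the
specimen (150 µm) as in any real reconstruction. Contact geometry:

- *full* / *none*: bone everywhere on the lateral shell / a marrow gap
  (max(150 µm, 3 voxels)) everywhere.
- *sector*: bone touches the shell inside an angular wedge covering the
  requested fraction of the circumference, marrow gap elsewhere.
- *trabecular*: bone is a Gaussian random field smoothed at the correlation
  length (default 150 µm, of the order of rat trabecular spacing) and
  thresholded to the bone volume fraction (default 0.35).

Grey values are class means (40/120/220, background < bone < implant) plus
an additive halo A·exp(−d/λ) outside the implant (A = 30, λ = 100 µm) —
a stand-in for residual beam hardening/metallic halation, not a physics
model — then Gaussian blur (σ = 25 µm) and Gaussian noise (σ = 8). One RNG
stream per phantom; identical seeds give bit-identical volumes. The
`exposed_top` flag leaves the top third of the implant outside the bone to
exercise the exclusion step.

The ground truth is computed from the clean labels before any artifact:
the fraction of lateral-shell faces adjacent to bone. Sector phantoms at
≥50-voxel implant diameter recover their nominal fraction within ~0.02 from
digitization alone.

What the phantom does *not* model: tomographic projection/reconstruction
(streaks, rings, cupping profiles beyond the exponential halo), photon
statistics, partial-volume spectra, implant surface roughness at the
micrometre scale, and anatomical cortical/trabecular architecture. Passing
ground-truth recovery here therefore shows the *measurement chain* is
unbiased under controlled artifacts, not that segmentation of any real scan
is correct.

Acquisition arithmetic: projections = (rotation/step)·frames (360°/0.75°·3 =
1,440) and nominal voxel size = detector pitch / magnification. The 50 µm
pitch used in examples is inferred: it is the unique pitch reproducing all
fifteen magnification→voxel-size calibration pairs of the reference scan
series to the printed 2 decimals.

## Statistics

Group summaries are mean ± SD (n−1). Group comparisons use the Mann-Whitney
U test; at the sample sizes these studies have (n = 4–6 per group) the
p-value is exact: all C(n₁+n₂, n₁) assignments are enumerated (midranks for
ties) and p = P(min(U, U′) ≤ observed) under the permutation null, which for
tie-free data equals the classical doubled-tail exact p. Combined n > 20
falls back to the normal approximation with tie correction. Homogeneity of
variance uses Levene's test with mean centers (W defined as 0 when all
absolute deviations coincide). The 2D-vs-3D method correlation is Pearson
by default — the natural choice for paired percentage measurements —
with Spearman behind a flag; no multiple-testing correction is applied by
default (a Holm option exists), matching common practice in small implant
studies.

## Problem sizes and tolerances

Default test and acceptance runs generate phantoms at 25 µm voxels
(120-voxel implant diameter, ~3.5M voxels; analysis at 50 µm after
resampling), with one 12.5 µm phantom for the resolution-stability check —
sizes chosen so the whole suite runs in minutes on one CPU while keeping
the implant diameter ≥50 voxels at analysis resolution. Isotropic spacing
is required throughout (reader tolerance 0.1%); DICOM millimetres are
converted to µm at the boundary. MetaImage is the canonical interchange
format; TIFF stacks carry spacing as ImageJ metadata and require an
explicit spacing otherwise.

## Known limitations

- The exclusion plane is axis-perpendicular in auto mode; oblique emergence
  needs an explicit plane.
- The 2D arm measures one traced profile per section; implants that split
  into multiple in-plane components keep only the largest.
- The halo is additive and isotropic; real beam hardening is
  direction- and spectrum-dependent.
- Exact Mann-Whitney enumeration is O(C(n₁+n₂, n₁)); fine up to combined
  n = 20, approximate beyond.
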