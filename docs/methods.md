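# Methods

## Model and procedure

`tdrm` treats a tractogram as a bag of polylines in world-mm coordinates and
reduces each streamline to three observables: the tissue label at its first
point, the tissue label at its last point, and its arc length (the sum of
Euclidean segment lengths of the stored polyline — no spline smoothing, which
matches fixed-step tractography output).  Everything downstream — rejection,
classification, density, asymmetry — is a function of these observables, so
the pipeline is deterministic given its inputs.

Tissue labels follow the conventional FreeSurfer-derived partition:
0 background, 1 white matter, 2 left cortex, 3 right cortex, 4 subcortical.
World points resolve to labels by the nearest-voxel convention
`floor(inverse(affine) · p + 0.5)`; points outside the array are background
by contract rather than an error, because real tractograms do contain such
terminals and the validation stage is the right place to reject them.

### Rejection and classification rules

1. Either terminal in white matter → reject as **noise**.
2. Otherwise, no terminal in cortex (labels 2/3) → reject as **ineffective**.
3. Of the validated tracks: any subcortical terminal → **projection**; one
   terminal in each cortex → **commissural**; both terminals in the same
   cortex → **association**, split at 60 mm arc length.
4. A validated track whose other terminal is background fits no category and
   is reclassified ineffective rather than given an invented class.

Precedences (noise over ineffective, projection over commissural over
association) are applied in that fixed order so every streamline receives
exactly one label.  The 60 mm boundary itself is assigned to the **long**
side: the defining phrases ("shorter than 6 cm", "longer than 6 cm") leave
exactly 60 mm open, and a half-open interval `[60, ∞)` keeps the split
deterministic.  A track of exactly 60.000 mm is therefore long, and 59.999 mm
short.

### Density

Track density is a raw terminal count per 1 mm³ voxel, one channel per
class, with no interpolation along the streamline and no smoothing: density
is defined as a count, and the conservation property (channel sums equal
counted terminals, exactly) is asserted throughout the test suite.  Two
counting modes exist because projection fibers have only one cortical
terminal: *all-terminals* (default for voxel maps — the subcortical endpoint
of projection tracks is part of the volumetric picture) and *cortical-only*
(default for parcel tables, which assess the cerebral cortex alone).  In
cortical-only mode, equal numbers of projection and commissural tracks yield
a cortical terminal ratio of exactly 1/2 — the single- versus
double-terminal geometry, reproduced exactly by the phantom.

Parcel-level relative density is `tracks_amount / piece_volume_mm3`, with
`piece_volume` measured from the parcellation affine so densities are
comparable across grids.  Terminals falling in unlabeled voxels are tallied
to an explicit `unassigned` row instead of being silently dropped.  Terminals
on parcel boundaries follow the same nearest-voxel rule as every other
lookup; no splitting or smoothing.

### Intensity transform and rendering

Display intensity is `1 − exp(−k · density / max_density)`; k defaults to 30
(voxel RGB), 8 (parcel RGB) and 2 (grayscale total).  `max_density` is
resolved globally over the composed channels by default — a single dmax
preserves cross-class comparability at each voxel (if class a outnumbers
class b at a voxel, channel a is brighter); per-channel normalization is
available as an option.  The association-only two-color map reuses the k of
its level (30 voxel / 8 parcel) since no separate constant is specified for
it; this is an assumption, recorded here.

Projections stack slices far-to-near per view and paint a pixel only when
the voxel's pre-transform total density exceeds a threshold (default 0, i.e.
"total count > 0" — the volume minimum in practice), which removes the black
background and sub-threshold noise from the composite.  Medial views mask to
one hemisphere by the world-x sign of voxel centers and stack from the
lateral side toward the midline, so the interhemispheric face remains
visible.  Rasters are written as 8-bit PNG with `round(255·v)`; the float
NIfTI/TSV artifacts retain full precision.

### Group analysis

Averaging operates on densities (float mean per voxel and channel), with the
color transform applied *after* averaging.  Per-parcel group statistics are
means and sample SDs (ddof = 1) across subjects; hemisphere-level summaries
are unweighted means over the labels of each hemisphere (a volume-weighted
option would change the numbers; unweighted is the default because parcel
tables already normalize by piece volume).

The asymmetry test is a paired two-sided t-test across subjects on LH−RH
differences.  No specific test is mandated by the density definition itself;
the paired t-test matches the structure of per-subject hemisphere pairs, and
a Wilcoxon signed-rank variant is exposed for non-normal data.  For a
multi-label region each subject contributes **one** pair — the unweighted
mean over the region's labels per hemisphere — keeping observations
independent rather than pooling subjects × labels.  Homotopic pairing is by
parcel name (same name on both hemispheres; the phantom uses the odd/even
label convention).  Degenerate inputs are reported, not hidden: all-zero
differences give p = 1, and a zero-variance nonzero difference is flagged
`degenerate` with p = NaN.  Raw p-values are reported; multiple-testing
correction is left to the caller.  The subject-level outlier screen codifies
"anomalous totals or commissural ratios" as median ± 3.5·MAD on both
metrics; it is advisory only and never auto-excludes.

## Phantom

The phantom emulates the *compartment structure* the classifier depends on:
an ellipsoidal brain with two cortical shells (~2.5 mm thick) split by a
2-voxel interhemispheric fissure at x = 0, white matter filling each
hemisphere, and a central subcortical sphere straddling the midline.  The
parcellation tiles each shell into contiguous angular wedges about the
left–right axis (odd labels left, even labels right, cyclic lobe-group
assignment).  Default grid: 80³ voxels at 1 mm.

Streamlines are built from control points — terminals sampled on voxel
centers of the class-defining compartments, interior waypoints pulled into
deep white matter and pushed off the subcortical blob — jittered, then
resampled at 0.2 mm steps (the step size of the tractography the phantom
stands in for).  Long-association tracks that fall short of 60 mm are
inflated by a tangential zigzag between their waypoints until the arc
exceeds 62 mm; short-association pairs are sampled within a 40 mm chord and
verified below 56 mm, so both classes clear the boundary with margin rather
than by rejection sampling at the threshold.  Everything is driven by one
`numpy` generator seeded from the spec, so identical seeds give byte-identical
TCK output.

What the phantom does **not** emulate: diffusion signal, fiber orientation
distributions, curvature statistics, partial-volume effects, and gyral bias
(real tractography preferentially terminates on gyral crowns).  Passing the
phantom tests therefore demonstrates that the bookkeeping — endpoint lookup,
rules, counting, rendering, statistics — is exact, not that the upstream
tractography is anatomically faithful.  Real-data headline numbers (millions
of tracks, ~90 % exclusion rates, specific regional asymmetries) depend on
the tractography and cohort and are outside what a phantom can certify.

## Numerical choices and problem sizes

- Nearest-voxel rounding uses `floor(x + 0.5)` (round-half-up), not banker's
  rounding, so the convention is stable across platforms.
- The acceptance analyses use a 10,000-track phantom (plus 1,500 planted
  rejects) for classification recovery, a 60³ scene for the half-density
  ratio, a 40³ scene for the renderer-versus-loop comparison, and 1,000
  replicates of 16 subjects for the calibration of the paired test; these
  sizes make every check exact or tightly bounded while keeping a full run
  in the seconds-to-minutes range on one core.
- Streamline coordinates are stored float32 in TCK (the format's datatype);
  all internal arithmetic is float64.
- Empty inputs are contracts, not crashes: zero validated tracks yield
  undefined (None) fractions, an all-zero density volume renders black with
  a warning, and an empty histogram is empty.

## Known limitations

- The classifier trusts the segmentation: a misplaced tissue label
  misclassifies every streamline terminating in it.
- `space_id` is a tag, not a registration check — group averaging verifies
  grid shape and affine but cannot detect subtly misaligned inputs.
- TCK is the only streamline dialect read or written (no TRK/VTK).
- Parcel assignment is nearest-voxel; terminals within half a voxel of a
  parcel boundary are not split or weighted.
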