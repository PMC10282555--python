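# Methods

## Model and assumptions

The package assigns microstructural metrics carried by *fixels* (per-voxel
fiber populations, each with a principal orientation, a volume fraction and
named scalar metrics) to the streamlines of a macroscopic tract. Its core
assumptions are:

- streamline segments are straight between consecutive points; each segment
  is subdivided at voxel boundaries and every intra-voxel piece inherits the
  parent segment's direction (for straight segments, per-piece re-orientation
  would be identical);
- fixel orientations and segment directions are *axial*: v and −v describe
  the same physical orientation, so all angles are computed as
  arccos(|u·v|) ∈ [0°, 90°]. This convention is what makes the angular
  weighting's φ = min(90°, Σθ) cap meaningful;
- the contribution of a voxel's fixels to a segment is a convex combination:
  α ∈ [0,1]^K with Σα = 1, so every derived quantity (segment metric, map
  value, tract mean) is bounded by the input metric range.

Three contribution strategies are implemented: relative-volume (`vol`),
closest-fixel-only (`cfo`) and angular weighting (`ang`). Two tract-mean
weightings are implemented: total-segment-length (`tsl`, voxels weighted by
the summed in-voxel streamline length) and region-of-interest (`roi`, equal
weight on every voxel the streamlines touch).

## Numerical and edge-case choices

- **cfo ties** (two fixels at the same angle) resolve to the lowest fixel
  index, keeping maps deterministic and bit-reproducible.
- **ang degenerate denominator** (all angles equal, including all fixels
  aligned with the segment): the continuity limit is the uniform split 1/K,
  which is what is returned when the denominator falls below 1e-12.
- **Absent fixels**: a fixel slot with volume fraction ≤ 0 or orientation
  norm < 1e-8 is excluded from the voxel's effective fixel count; multi-fixel
  model outputs conventionally pad unused slots with zeros. Fixel-free (CSF)
  voxels yield NaN map values and are excluded from tract means under both
  weightings so they cannot dilute white matter averages.
- **Voxel convention**: voxel (i,j,k) is the half-open box
  [i−0.5, i+0.5) × ... in voxel coordinates (centers at integer coordinates).
  Boundary subdivision uses parametric ray marching against the half-integer
  boundary planes; piece voxels are assigned from the piece midpoint, so
  measure-zero corner touches resolve deterministically to one neighbor.
  Subsegment lengths are measured in world mm and sum to the segment length
  to 1e-9 relative.
- **Out-of-volume pieces** are flagged and excluded from maps (never an
  error): real tractograms routinely brush mask edges.
- **Angles are computed in world (RAS mm) space**; fixel peaks are stored in
  world space and anisotropic voxels would distort voxel-space angles.
- **roi membership** is defined by streamline presence (total segment length
  > 0); an optional minimum-length threshold (default 0 mm) can suppress
  voxels only grazed by a few segments.
- **Scan–rescan percentage change** uses the symmetric (Bland–Altman)
  denominator, 100·(m2 − m1)/((m1+m2)/2), which is antisymmetric under
  swapping the scans; the sample SD is undefined (NaN) for a single pair.
- **Accumulation** over subsegments is sequential in traversal order, so all
  maps are bit-reproducible run to run.

Two independent aggregation routes exist on purpose: the fixel-aggregated
map/mean (via fixel weight maps) and the segment-aggregated route (summing
l·M_vs per voxel). They are algebraically identical; the test suite holds
them to 1e-9 agreement on jittered phantoms as a standing cross-check.

## The synthetic phantom

The phantom emulates, at the fixel level, a 2D crossing geometry: a
32×32×1 grid of 2 mm isotropic voxels holding two horizontal tracts (T1 rows
20–23, FVF 0.70, FA 0.80; T2 rows 8–11, FVF 0.66, FA 0.75) crossed by two
vertical tracts (T3 columns 8–11, T4 columns 20–23) whose FVF rises linearly
from 0.40 at the top row to 0.70 at the bottom (FA 0.45→0.65); all other
voxels are CSF with no fixels. Crossing voxels hold both tracts' fixels at
orthogonal orientations with fractions 0.5/0.5; single-tract voxels hold one
fixel at fraction 0.7. Each tract carries 50 straight streamlines at 1 mm
step spanning the grid, offset to cover the band cross-section (inset a
quarter voxel from band edges so no streamline rides a voxel boundary).
Optional orientation jitter (SD in degrees, seeded) perturbs each fixel
orientation. The horizontal FA values and the vertical FVF/FA endpoints are
package defaults — plausible deep-white-matter values — and are configurable;
the FVF values 0.70/0.66 are the phantom's defining ground truths.

The diffusivity parameters recorded in the manifest (intra-axonal
2.0 μm²/ms, extracellular 1.0 μm²/ms, gamma-distributed axon diameters of
mean 1.0 μm and variance 0.6 μm) are provenance of the signal-level phantom
this geometry mirrors; no diffusion signal is simulated — the package
consumes fixels, so fixel-level ground truth exercises every computation.

The corruption operator models a multi-fixel estimation error: in a chosen
region, each single fixel is replaced by two fixels tilted ±half the split
angle about an axis perpendicular to the true orientation (the slice normal
for in-plane fixels), fractions halved, and each named metric offset by +δ
on the first fixel and −δ on the second. The manifest ground truth is
unchanged — the corruption is an estimation error, not a tissue change. For
an on-axis segment the two corrupted fixels tie in angle, so `cfo` takes the
+δ fixel (overestimation) while `ang` splits 0.5/0.5 and cancels the offsets.

What the phantom does *not* emulate: curved or fanning geometry, noise on
the metrics, partial-volume fraction estimation error, probabilistic
streamline dispersion, and realistic fixel-count misestimation beyond the
symmetric split. Passing tests therefore demonstrate the correctness of the
aggregation machinery and the qualitative strategy ordering, not robustness
to every artifact of real acquisitions.

## Problem sizes

The default phantom (32×32 grid, 50 streamlines/tract, ~3,100 subsegments
per horizontal tract) runs the full pipeline in well under a second; the
normalization probe samples 12,000 random voxel-segment configurations.
These sizes give exact (to 1e-9) checks of all algebraic identities while
keeping the whole suite fast.

## I/O conventions

Fixel fields travel as NIfTI-1 volumes: a peaks image (last dimension 3·K
xyz triplets, all-zero triplet = absent fixel, vectors re-normalized on load
when their norm is within [0.9, 1.1] and rejected otherwise), a fractions
image and one image per metric (last dimension K). All volumes must share
shape and affine to 1e-4. Streamlines are read/written as TRK or TCK via
nibabel and always handled in world RAS mm. NaN is the undefined-voxel
sentinel in float volumes; CSVs render it as an empty field. The peaks-style
single-file encoding was chosen over directory-per-fixel layouts for
simplicity; the loader is the one place a second dialect could be added.

## Known limitations

- Only the angular-weighting formula above is provided for all K; alternative
  contribution families that may suit K > 2 better are not implemented.
- No spatial regularization across neighboring fixels.
- No resampling of streamline step size: points are used as given.
- Group statistics are limited to the scan–rescan percentage-change summary;
  regression modeling of cohort effects is out of scope (any off-the-shelf
  linear model applies to the exported tract means).
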