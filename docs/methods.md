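# Methods

This note documents the models, parameter choices, numerical details and
known limitations of the `spheroquant` pipeline.

## Synthetic spheroid model

The 3D generator emulates a cleared, wholemount-stained spheroid imaged by
confocal microscopy on an anisotropic grid (default voxel spacing
1.0 × 0.473 × 0.473 µm in z, y, x — a typical 20× confocal configuration
with 1 µm z-steps). Cells are spheres with radii drawn from a truncated
normal distribution, placed by rejection sampling inside the spheroid
radius with no overlap; larger cells are placed first, which markedly
improves the achievable packing at a fixed attempt budget. Each cell holds
one concentric spherical nucleus scaled so the nuclear volume is a fixed
fraction of the cell volume — containment is guaranteed by construction.
When the requested density is not achievable the generator raises an error
naming the number of cells it could place, rather than silently returning
fewer.

Default conditions: 200 cells of mean radius 6 µm (≈905 µm³; nucleus
≈450 µm³ at volume fraction 0.5, comfortably inside the 300–3,000 µm³
debris filter) in a 60 µm spheroid, i.e. a packing fraction ≈0.2, which
rejection sampling reaches reliably. The grid always keeps ≥45 empty
voxels on every face so that 40 dilation iterations can never touch the
array border.

Intensities are assigned analytically per compartment and only then
degraded: the "yap" channel sets cytoplasm to a base value and the nucleus
to (programmed N/C ratio) × base above a constant background, so that with
no blur/noise the background-corrected compartment-mean ratio equals the
programmed value identically. The per-cell programmed ratio and base
intensity interpolate linearly between a centre value and a rim value in
the cell's distance to the rim; the defaults (N/C 1.0 at centre, 2.0 at
rim) encode a rim-high YAP-like activation gradient. Degradation is an
isotropic Gaussian blur in voxel space (default σ = 1 voxel) plus additive
Gaussian noise (default SD 5 a.u., ≈5% of signal). Ki-67⁺ cells are chosen
uniformly at random (a fixed count, `round(fraction · n)`), and the Ki-67
label object of a positive cell is its nucleus mask carrying the cell id.
All randomness flows from one `numpy` generator seeded by the spec, so
identical specs give voxel-identical output.

In-memory channels are float64: the exact-recovery contract is 1e-9
relative, and float32 quantisation alone would contribute ≈1e-7. Files
store float32.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: optical PSF anisotropy, depth-dependent signal
loss (handled at acquisition by z-compensation in the emulated protocol),
segmentation errors (labels are perfect by construction), non-spherical
cell shapes, and realistic nuclear-volume distributions. Recovery numbers
on synthetic data are therefore upper bounds on real-data performance;
the oracle-equivalence tests (mask arithmetic, closing, geometry) are,
by contrast, exact statements about the algorithms themselves.

The 2D brightfield generator paints a dark axis-aligned ellipse (the
spheroid) and disjoint dark satellite disks (dissociated cells/aggregates)
on a bright background with mild Gaussian noise; truth records the
analytic ellipse eccentricity, the equivalent-circle diameter from the
painted pixel area, and the satellite area fraction. Default satellite
diameters (14–30 px) are large enough to survive the 5-px Gaussian
smoothing the measurement applies. The cryosection generator builds a
CK14-like inner disk and an Involucrin-like outer annulus; the annulus
mean intensity is solved from the programmed integrated-density ratio
(the spheroid-area normalisation cancels in the ratio). Exactly three
planes carry the sharp image, the rest are heavily blurred copies.

## Measurement stages

**Brightfield morphometry.** Diameter is reported as the equivalent-circle
diameter from mask area rather than from fitted-ellipse axes: it is
moment-free, robust to boundary noise, and coincides with the axis-based
value for circles. Eccentricity comes from the mask's second central
moments (`regionprops`), which reproduces the analytic value for exact
ellipses. The loose-cell measurement interprets the 5–200 px "object
diameter" band as equivalent-circle diameter (the convention of
CellProfiler-style size gates) and uses the full image area as the
denominator of the percentage. Segmentation is Gaussian smoothing + Otsu
two-class thresholding with dark-on-bright polarity by default and an
`invert` flag; this replaces interactive pixel-classification tools, and
the synthetic images are designed so it suffices.

**Volume filter.** Bounds are inclusive: a nucleus of exactly 300 µm³
passes ("less than 300" is the exclusion). Thresholds are physical, so
voxel spacing is mandatory.

**Spheroid reconstruction.** The closing iterates on the voxel grid, not
in physical space, despite the ≈2.1:1 z anisotropy — this mirrors the
established procedure and is kept as a reproducibility choice; the spacing
is recorded alongside. Hole filling runs once after erosion, before
largest-component selection. Erosion uses border_value = 1 so the array
face never erodes the mask; under the generator's 45-voxel margin this is
unobservable, but it is the correct closing convention near borders, and a
warning is emitted when the margin is below iterations + 5. A nucleus
counts as "inside" the spheroid by its centroid voxel (partial-overlap
handling is otherwise ambiguous); the identities volume = void + nuclear
inside and density = count/volume hold exactly by construction.

**Nucleus↔cell matching.** The default overlap score is nucleus coverage
|N∩C|/|N| with threshold 0.5, not strict Jaccard: a nucleus occupying
half its cell's volume has IoU ≈ 0.5 at best, and typical nuclei score
well below any 0.5 IoU cut, which would match nothing. Strict `iou`
remains available and both metrics are tested; this is the module's main
interpretation risk and is deliberately configurable. Matching is greedy
one-to-one in descending score with ties broken by ascending cell id then
nucleus id — deterministic. Cells with empty cytoplasm or non-positive
background-corrected cytoplasmic mean are excluded and tallied in a QC
count rather than clamped, avoiding silent bias. Background uses the mean
(matching the mean-based compartment statistics); a median option exists.
Ki-67 objects are assigned to the cell containing the largest fraction of
their voxels when that fraction is ≥ 0.5 — a majority-overlap reading of
id alignment.

**Hull geometry.** The hull centre is the polyhedron's volume centroid,
computed from unsigned tetrahedra against an interior reference point
(Qhull facet orientation is not consistent, so signed volumes would
cancel); the mean of all centroids is available as an alternative centre.
The ray-surface intersection is computed in closed form from the hull's
supporting half-spaces — along the outward ray the exit parameter is the
smallest positive plane crossing, which for a convex polytope is the
unique boundary intersection; this avoids per-triangle edge-hit tie
handling entirely, and a Möller–Trumbore ray–triangle scan serves as the
independent cross-check in the tests. Centroids marginally outside the
hull (floating error) clamp to distance 0. The distance error against a
continuum surface is bounded by the facet sag of the hull; at 500 surface
points the mean sag is ≈1% of the radius, with a worst-case facet around
2.5%.

**Cryosection.** The focus score is the variance of a discrete Laplacian —
standard and parameter-free; the top-3 planes need not be adjacent. The
channel threshold is Otsu's two-class method (consistent with the
brightfield stage), and the manual whole-spheroid wand selection is
replaced by automated thresholding + closing + hole filling of the
Involucrin channel. Note the radius-2 median filter legitimately rounds
off single-pixel corners of aliased shapes; segment-area contracts in the
tests are stated accordingly.

## Orchestration and reproducibility

`run_all` executes generator → volumetrics → subcellular → spatial,
writing TIFF volumes (spacing and payload kind embedded as JSON in the
image description tag), per-cell and summary CSVs, the resolved config
(YAML, excluding the self-referential output path), and last a manifest
with SHA-256 checksums of every output. Identical configs and seeds
reproduce identical checksums; this is asserted in the tests. Volumes are
written as plain multi-page TIFF rather than OME-TIFF because the OME
writer embeds a fresh UUID per file, which would defeat checksum
reproducibility; ImageJ-style spacing metadata is also understood on read.

## Problem sizes

Tests run on a 25-cell clean spheroid (exact-recovery regime), the
200-cell default spheroid with blur and noise (degraded regime), a 128³
packed-nuclei fixture for the closing reference check, and 15–30-cell
runs for end-to-end determinism; `scripts/acceptance.py` uses the
200-cell default conditions. These sizes keep every stage's behaviour
identical to larger volumes (all operations are per-voxel or per-object)
while staying comfortably within a single-CPU budget.

## Known limitations

- One nucleus per cell; multinucleated cells are outside the matching
  model.
- The closing's 40-iteration count is tied to the emulated pixel pitch
  (0.473 µm); other magnifications may need rescaling, which the API
  exposes but does not automate.
- Centroid-based "inside" counting can differ from any-overlap counting
  for nuclei straddling the mask boundary; the choice is recorded and the
  membership rule is a single place in the code.
- The spatial stage assumes a convex spheroid outline; invaginated or
  budding aggregates would need alpha-shapes, which are out of scope.
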