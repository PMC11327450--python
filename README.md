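# spheroquant

Quantitative image analysis of 3D spheroid cultures.

Scaffold-free spheroids grown in ultra-low-attachment plates are a standard
3D culture model, but comparing them across conditions requires
quantification at several scales at once: whole-spheroid morphometry from
brightfield plate scans, single-cell volumetrics from cleared confocal
stacks, subcellular marker localisation, and spatial organisation within
the aggregate. `spheroquant` implements that full chain for users with
segmented microscopy data (instance-label masks for nuclei, whole cells and
Ki-67 objects, e.g. from Cellpose) plus the raw fluorescence channels — and
ships a synthetic-data generator with exact ground truth so every stage can
be exercised and validated without any microscopy download.

## What it computes

**2D brightfield morphometry.** The main spheroid is segmented by Otsu
two-class thresholding; its size is reported as the equivalent-circle
diameter d = 2·√(A/π) and its shape as the moment-based ellipse
eccentricity e = √(1 − b²/a²) ∈ [0, 1). Dissociated cells and satellite
aggregates around the spheroid are segmented after a 5-pixel Gaussian
smoothing, kept when their equivalent diameter lies in a 5–200 px band
(which excludes the core spheroid), and summarised as the percentage of
image area they occupy.

**3D volumetrics.** Segmented nuclei are filtered by physical volume
(defaults 300–3,000 µm³; anything outside is treated as debris or a
segmentation error). The whole-spheroid mask is reconstructed from the
nuclear masks by morphological closing — 40 iterations of binary dilation
followed by 40 of erosion with a connectivity-1 (6-neighbourhood)
structuring element — then hole filling and largest-component selection.
From the mask: spheroid volume, nuclei density (nuclei inside / volume),
the internal void region (mask volume minus nuclear volume), and the Ki-67
proliferation index (100 · Ki-67⁺ cells / nuclei).

**Subcellular N/C ratios.** Nuclei are matched one-to-one to whole-cell
masks by overlap score (nucleus coverage |N∩C|/|N| by default, strict IoU
optionally), cytoplasm masks are derived by subtraction with the same ids,
and per-cell compartment means are background-corrected (background = mean
over all voxels outside the detected cells). The nuclear-to-cytoplasmic
ratio of a marker such as YAP1,

    N/C = (mean_nuc − background) / (mean_cyto − background),

is the readout for nuclear translocation.

**Spatial profiling.** A convex hull is built around all cell centroids;
for each cell a ray from the hull's volume centroid through the cell
centroid is intersected with the hull surface, and the distance from that
intersection to the centroid is the cell's depth below the spheroid rim.
Joined with N/C ratios and Ki-67 status this yields radial profiles.

**Cryosection differentiation.** From two-channel (Involucrin/CK14)
z-stacks the three most in-focus planes (variance-of-Laplacian score) are
summed, each channel is segmented after a radius-2 median filter, and the
integrated density (mean intensity × segment area normalised to spheroid
area) ratio Involucrin/CK14 quantifies epidermal differentiation.

## Worked example

Generate a small synthetic spheroid (30 cells, rim-high YAP-like gradient,
realistic blur and noise) and run the 3D chain:

```python
import numpy as np
from spheroquant import synthetic, subcellular as sub, volumetrics3d as v3d, spatial as sp

spec = synthetic.SyntheticSpec3D(seed=7, spheroid_radius_um=32.0, n_cells=30)
sph = synthetic.generate_spheroid(spec)

filtered, records = v3d.filter_nuclei(sph.nucleus_labels)
mask = v3d.reconstruct_spheroid_mask(filtered)
vol = v3d.compute_density_and_void(mask, filtered)
print(f"spheroid volume : {vol.volume_um3:.3e} um^3")
print(f"density         : {vol.density_per_um3 * 1e5:.2f} nuclei / 1e5 um^3")
print(f"void fraction   : {100 * vol.void_volume_um3 / vol.volume_um3:.1f} %")

matches = sub.match_nuclei_to_cells(filtered, sph.cell_labels)
cyto = sub.derive_cytoplasm(sph.cell_labels, filtered, matches)
bg = sub.background_level(sph.channels["yap"], sph.cell_labels)
ki67 = sub.assign_ki67(sph.ki67_labels, sph.cell_labels)
recs, qc = sub.compartment_means_and_ratio(
    sph.channels["yap"], filtered, cyto, matches, bg, ki67)
cells = sub.records_to_frame(recs)
print(f"Ki-67 positive  : {v3d.ki67_fraction(len(ki67), len(records)):.1f} %")

cents = sph.cell_labels.centroids_um()
hull = sp.build_hull(np.array([cents[i] for i in sorted(cents)]))
d = sp.distances_to_hull(hull, np.array([cents[i] for i in cells.cell_id]))
print(sp.radial_profile(cells.assign(distance_to_hull_um=d), 2).round(3))
```

prints

```
spheroid volume : 4.477e+04 um^3
density         : 60.30 nuclei / 1e5 um^3
void fraction   : 74.0 %
Ki-67 positive  : 30.0 %
 bin_center_um  mean_nc_ratio  median_nc_ratio  ki67_positive_fraction   n
         3.675          1.847            1.850                   0.292  24
        11.024          1.589            1.606                   0.333   3
```

The density says 27 nuclei share ≈4.5 × 10⁴ µm³ of reconstructed spheroid;
74% of that volume is non-nuclear (cytoplasm, organelles, extracellular
space). The radial profile recovers the programmed rim-high gradient: cells
in the outer bin (shallow, near the hull) average N/C ≈ 1.85, the deeper
cells ≈ 1.59.

The same stages are available from the shell:

```
spheroquant run-all --out run1 --seed 7
spheroquant simulate2d --out bf --seed 3
spheroquant morphometry2d bf/brightfield.tif --out table.csv --pixel-size 0.65
```

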