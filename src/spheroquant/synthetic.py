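"""Synthetic spheroid data with known ground truth.

Generates the three kinds of input the quantification chain consumes:

* 3D cleared-spheroid confocal stacks — densely packed spherical cells, each
  with one concentric nucleus, instance-label volumes for cells / nuclei /
  Ki-67 objects, and fluorescence channels ("dapi", "yap", "ki67") whose
  per-cell nuclear-to-cytoplasmic intensity ratios are programmed exactly;
* 2D brightfield plate scans — a dark elliptical spheroid on a bright
  background plus satellite aggregates of dissociated cells;
* two-channel cryosection z-stacks with a programmed integrated-density
  ratio and a known set of in-focus planes.

Every generator draws all randomness from a single ``numpy`` generator
seeded by the spec, so identical specs yield voxel-identical output.
Intensities are assigned analytically per compartment and only then
optionally blurred and noised, which lets tests separate algorithmic error
from imaging degradation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .volumes import DEFAULT_SPACING_UM, IntensityVolume, LabeledVolume

#: border kept free of labels so 40 closing iterations never touch a face
BORDER_MARGIN_VOX = 45


class PackingError(RuntimeError):
    """Raised when rejection sampling cannot place the requested cells."""


# ---------------------------------------------------------------------------
# 3D spheroid
# ---------------------------------------------------------------------------


@dataclass
class SyntheticSpec3D:
    """Parameters of a synthetic 3D spheroid stack.

    Lengths are micrometres.  The voxel grid is sized automatically so the
    spheroid sits at the volume centre with at least ``BORDER_MARGIN_VOX``
    empty voxels on every face.  Cells are spheres placed by rejection
    sampling without overlap; the nucleus is a concentric sphere scaled to
    ``nucleus_volume_fraction`` of the cell volume.  The "yap" channel is
    built so that, before blur and noise, each cell's background-corrected
    nuclear/cytoplasmic mean ratio equals the programmed value obtained by
    linear interpolation between ``nc_ratio_center`` and ``nc_ratio_rim``
    in the cell's distance to the spheroid rim.
    """

    seed: int = 0
    voxel_spacing_um: tuple[float, float, float] = DEFAULT_SPACING_UM
    spheroid_radius_um: float = 60.0
    n_cells: int = 200
    cell_radius_um_mean: float = 6.0
    cell_radius_um_sd: float = 0.5
    nucleus_volume_fraction: float = 0.5
    ki67_fraction: float = 0.3
    nc_ratio_center: float = 1.0
    nc_ratio_rim: float = 2.0
    yap_cyto_intensity_center: float = 80.0
    yap_cyto_intensity_rim: float = 120.0
    background_level: float = 10.0
    noise_sd: float = 5.0
    blur_sigma_vox: float = 1.0
    max_attempts_per_cell: int = 5000

    def __post_init__(self) -> None:
        if self.spheroid_radius_um <= 0 or self.cell_radius_um_mean <= 0:
            raise ValueError("lengths must be positive")
        if any(s <= 0 for s in self.voxel_spacing_um):
            raise ValueError("voxel spacing must be positive")
        if not 0.0 <= self.ki67_fraction <= 1.0:
            raise ValueError("ki67_fraction must lie in [0, 1]")
        if not 0.0 < self.nucleus_volume_fraction <= 1.0:
            raise ValueError("nucleus_volume_fraction must lie in (0, 1]")
        if self.nc_ratio_center <= 0 or self.nc_ratio_rim <= 0:
            raise ValueError("programmed N/C ratios must be positive")
        if self.n_cells < 1:
            raise ValueError("n_cells must be at least 1")
        if self.cell_radius_um_sd < 0 or self.noise_sd < 0 or self.blur_sigma_vox < 0:
            raise ValueError("spreads must be non-negative")

    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(
            int(np.ceil(2.0 * self.spheroid_radius_um / s)) + 2 * BORDER_MARGIN_VOX
            for s in self.voxel_spacing_um
        )


@dataclass
class SyntheticSpheroid:
    """Generator output: label volumes, channels and the ground-truth table.

    Nucleus and Ki-67 objects carry the same integer id as their parent
    cell.  ``truth`` has one row per cell: id, centroid (µm), cell and
    nucleus volumes (µm³), programmed N/C ratio, Ki-67 status and distance
    to the spheroid rim (µm).
    """

    cell_labels: LabeledVolume
    nucleus_labels: LabeledVolume
    ki67_labels: LabeledVolume
    channels: dict[str, IntensityVolume]
    truth: pd.DataFrame
    spec: SyntheticSpec3D


def _pack_spheres(
    rng: np.random.Generator, spec: SyntheticSpec3D
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample non-overlapping sphere centres inside the spheroid.

    Returns (centers_um[n, 3], radii_um[n]) in physical (z, y, x)
    coordinates relative to the spheroid centre.
    """
    R = spec.spheroid_radius_um
    all_radii = np.clip(
        rng.normal(spec.cell_radius_um_mean, spec.cell_radius_um_sd, spec.n_cells),
        0.25 * spec.cell_radius_um_mean,
        2.0 * spec.cell_radius_um_mean,
    )
    # place large cells first: markedly better packing at equal attempt budget
    all_radii = np.sort(all_radii)[::-1]
    centers: list[np.ndarray] = []
    radii: list[float] = []
    for i, r in enumerate(map(float, all_radii)):
        placed = False
        for _ in range(spec.max_attempts_per_cell):
            # uniform point in the admissible sphere of radius R - r
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            rad = (R - r) * rng.uniform() ** (1.0 / 3.0)
            c = u * rad
            if all(
                np.linalg.norm(c - c0) > r + r0 + 1e-9 for c0, r0 in zip(centers, radii)
            ):
                centers.append(c)
                radii.append(r)
                placed = True
                break
        if not placed:
            raise PackingError(
                f"could only place {i} of {spec.n_cells} cells of mean radius "
                f"{spec.cell_radius_um_mean} µm inside a {R} µm spheroid; "
                "reduce n_cells or enlarge the spheroid"
            )
    return np.array(centers), np.array(radii)


def _paint_sphere(
    labels: np.ndarray,
    center_vox_um: np.ndarray,
    radius_um: float,
    spacing: np.ndarray,
    label: int,
) -> int:
    """Set voxels whose physical centre lies within the sphere; return count."""
    lo = np.maximum(np.floor((center_vox_um - radius_um) / spacing).astype(int), 0)
    hi = np.minimum(
        np.ceil((center_vox_um + radius_um) / spacing).astype(int) + 1,
        np.array(labels.shape),
    )
    zz, yy, xx = np.meshgrid(
        np.arange(lo[0], hi[0]) * spacing[0] - center_vox_um[0],
        np.arange(lo[1], hi[1]) * spacing[1] - center_vox_um[1],
        np.arange(lo[2], hi[2]) * spacing[2] - center_vox_um[2],
        indexing="ij",
    )
    inside = zz * zz + yy * yy + xx * xx <= radius_um * radius_um
    region = labels[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    region[inside] = label
    return int(inside.sum())


def generate_spheroid(spec: SyntheticSpec3D) -> SyntheticSpheroid:
    """Generate a packed synthetic spheroid stack with ground truth.

    Deterministic for a fixed spec (all randomness flows from ``spec.seed``).
    Raises :class:`PackingError` when the spheroid is too small for the
    requested cell count.
    """
    rng = np.random.default_rng(spec.seed)
    spacing = np.asarray(spec.voxel_spacing_um, dtype=float)
    shape = spec.grid_shape()
    grid_center_um = (np.array(shape) - 1) / 2.0 * spacing

    centers_rel, radii = _pack_spheres(rng, spec)
    centers_um = centers_rel + grid_center_um

    cell_labels = np.zeros(shape, dtype=np.int32)
    nucleus_labels = np.zeros(shape, dtype=np.int32)
    nuc_scale = spec.nucleus_volume_fraction ** (1.0 / 3.0)

    cell_counts, nuc_counts = [], []
    for i, (c, r) in enumerate(zip(centers_um, radii), start=1):
        cell_counts.append(_paint_sphere(cell_labels, c, r, spacing, i))
        nuc_counts.append(_paint_sphere(nucleus_labels, c, r * nuc_scale, spacing, i))

    # programmed radial profiles (distance to rim: R at centre, 0 at rim)
    R = spec.spheroid_radius_um
    d_rim = R - np.linalg.norm(centers_rel, axis=1)
    frac_center = np.clip(d_rim / R, 0.0, 1.0)  # 1 at centre, 0 at rim
    nc_true = spec.nc_ratio_rim + (spec.nc_ratio_center - spec.nc_ratio_rim) * frac_center
    cyto_base = spec.yap_cyto_intensity_rim + (
        spec.yap_cyto_intensity_center - spec.yap_cyto_intensity_rim
    ) * frac_center

    n_pos = int(round(spec.ki67_fraction * spec.n_cells))
    pos_ids = rng.choice(np.arange(1, spec.n_cells + 1), size=n_pos, replace=False)
    ki67_status = np.zeros(spec.n_cells, dtype=bool)
    ki67_status[pos_ids - 1] = True

    ki67_labels = np.where(
        np.isin(nucleus_labels, pos_ids), nucleus_labels, 0
    ).astype(np.int32)

    # analytic per-compartment intensities, then degradation
    voxel_volume = float(np.prod(spacing))
    nuc_mask = nucleus_labels > 0
    cyto_mask = (cell_labels > 0) & ~nuc_mask

    yap = np.full(shape, float(spec.background_level), dtype=np.float64)
    cyto_amp = np.zeros(spec.n_cells + 1)
    nuc_amp = np.zeros(spec.n_cells + 1)
    cyto_amp[1:] = cyto_base
    nuc_amp[1:] = nc_true * cyto_base
    yap[cyto_mask] = spec.background_level + cyto_amp[cell_labels[cyto_mask]]
    yap[nuc_mask] = spec.background_level + nuc_amp[nucleus_labels[nuc_mask]]

    dapi = np.full(shape, float(spec.background_level), dtype=np.float64)
    dapi[nuc_mask] += 150.0
    ki67_ch = np.full(shape, float(spec.background_level), dtype=np.float64)
    ki67_ch[ki67_labels > 0] += 150.0

    channels = {}
    for name, img in (("dapi", dapi), ("yap", yap), ("ki67", ki67_ch)):
        if spec.blur_sigma_vox > 0:
            img = ndi.gaussian_filter(img, sigma=spec.blur_sigma_vox)
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=shape)
        channels[name] = IntensityVolume(np.asarray(img, dtype=np.float64), tuple(spacing))

    truth = pd.DataFrame(
        {
            "id": np.arange(1, spec.n_cells + 1),
            "centroid_z_um": centers_um[:, 0],
            "centroid_y_um": centers_um[:, 1],
            "centroid_x_um": centers_um[:, 2],
            "cell_volume_um3": np.array(cell_counts) * voxel_volume,
            "nucleus_volume_um3": np.array(nuc_counts) * voxel_volume,
            "true_nc_ratio": nc_true,
            "ki67_status": ki67_status,
            "true_distance_to_rim_um": d_rim,
        }
    )

    sp = tuple(spacing)
    return SyntheticSpheroid(
        cell_labels=LabeledVolume(cell_labels, sp),
        nucleus_labels=LabeledVolume(nucleus_labels, sp),
        ki67_labels=LabeledVolume(ki67_labels, sp),
        channels=channels,
        truth=truth,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# 2D brightfield
# ---------------------------------------------------------------------------


@dataclass
class SyntheticSpec2D:
    """Parameters of a synthetic brightfield plate scan.

    The main spheroid is a dark, axis-aligned ellipse at the image centre;
    satellites are small dark disks placed disjointly from the main object
    and from one another, emulating dissociated cells and loose aggregates.
    """

    seed: int = 0
    pixel_size_um: float = 0.65
    main_axes_px: tuple[float, float] = (160.0, 120.0)  # (major, minor) full axes
    n_satellites: int = 20
    satellite_diameter_px_range: tuple[float, float] = (14.0, 30.0)
    image_shape: tuple[int, int] | None = None
    background_value: float = 220.0
    foreground_value: float = 60.0
    noise_sd: float = 3.0
    max_attempts_per_satellite: int = 2000

    def __post_init__(self) -> None:
        major, minor = self.main_axes_px
        if minor < 4 or major < minor:
            raise ValueError("main axes must satisfy major >= minor >= 4 px")
        lo, hi = self.satellite_diameter_px_range
        if not 0 < lo <= hi:
            raise ValueError("satellite diameter range must be positive and ordered")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")

    def resolved_shape(self) -> tuple[int, int]:
        if self.image_shape is not None:
            return self.image_shape
        side = int(np.ceil(self.main_axes_px[0] * 2.5))
        return (side, side)


def generate_brightfield(spec: SyntheticSpec2D) -> tuple[np.ndarray, dict]:
    """Generate a brightfield image and its morphometric ground truth.

    Returns ``(image, truth)`` where truth holds the equivalent-circle
    ``diameter_um`` and analytic ``eccentricity`` of the main ellipse, the
    achieved ``loose_area_fraction`` (satellite pixels / image pixels, in
    [0, 1]) and the painted pixel areas.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.resolved_shape()
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0

    a = spec.main_axes_px[0] / 2.0  # semi-major (x)
    b = spec.main_axes_px[1] / 2.0  # semi-minor (y)
    main = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0

    sat_mask = np.zeros(shape, dtype=bool)
    # keep satellites clear of the main object and the image border
    forbidden = ndi.binary_dilation(main, iterations=5)
    lo, hi = spec.satellite_diameter_px_range
    for _ in range(spec.n_satellites):
        placed = False
        for _ in range(spec.max_attempts_per_satellite):
            d = rng.uniform(lo, hi)
            r = d / 2.0
            y0 = rng.uniform(r + 2, shape[0] - r - 2)
            x0 = rng.uniform(r + 2, shape[1] - r - 2)
            disk = (yy - y0) ** 2 + (xx - x0) ** 2 <= r * r
            pad = (yy - y0) ** 2 + (xx - x0) ** 2 <= (r + 2) ** 2
            if not (pad & (forbidden | sat_mask)).any():
                sat_mask |= disk
                placed = True
                break
        if not placed:
            raise PackingError("could not place all satellites disjointly")

    image = np.full(shape, spec.background_value, dtype=np.float64)
    image[main | sat_mask] = spec.foreground_value
    if spec.noise_sd > 0:
        image += rng.normal(0.0, spec.noise_sd, size=shape)

    area_px = int(main.sum())
    truth = {
        "diameter_um": 2.0 * np.sqrt(area_px / np.pi) * spec.pixel_size_um,
        "eccentricity": float(np.sqrt(1.0 - (b / a) ** 2)),
        "loose_area_fraction": float(sat_mask.sum()) / sat_mask.size,
        "main_area_px": area_px,
        "satellite_area_px": int(sat_mask.sum()),
    }
    return image.astype(np.float32), truth


# ---------------------------------------------------------------------------
# 2D cryosection z-stacks
# ---------------------------------------------------------------------------


def generate_cryosection(
    seed: int,
    n_z: int = 9,
    programmed_ratio: float = 2.0,
    spheroid_radius_px: int = 80,
    focused_plane_indices: tuple[int, int, int] | None = None,
    noise_sd: float = 0.0,
    image_shape: tuple[int, int] | None = None,
) -> tuple[dict[str, np.ndarray], dict]:
    """Generate a two-channel cryosection z-stack with a programmed
    Involucrin/CK14 integrated-density ratio.

    The sharp section image places a CK14-like inner disk and an
    Involucrin-like outer annulus inside the spheroid disk; annulus mean
    intensity is chosen so that (mean × area) of the Involucrin segment is
    ``programmed_ratio`` times that of the CK14 segment (the spheroid-area
    normalisation cancels in the ratio).  Exactly three planes carry the
    sharp image; the rest are heavily blurred copies.

    Returns ``({"involucrin": stack, "ck14": stack}, truth)`` with stacks of
    shape ``(n_z, H, W)``.
    """
    if n_z < 3:
        raise ValueError("n_z must be at least 3")
    if programmed_ratio <= 0:
        raise ValueError("programmed_ratio must be positive")
    rng = np.random.default_rng(seed)
    if focused_plane_indices is None:
        mid = n_z // 2
        focused_plane_indices = (mid - 1, mid, mid + 1)
    focused = tuple(sorted(int(i) for i in focused_plane_indices))
    if len(focused) != 3 or min(focused) < 0 or max(focused) >= n_z:
        raise ValueError("exactly three focused plane indices within the stack required")

    shape = image_shape or (int(spheroid_radius_px * 2.6),) * 2
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    rr = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)

    R = float(spheroid_radius_px)
    ck14_seg = rr <= 0.5 * R
    inv_seg = (rr >= 0.62 * R) & (rr <= R)

    ck14_mean = 100.0
    inv_mean = programmed_ratio * ck14_mean * ck14_seg.sum() / inv_seg.sum()

    inv_sharp = np.zeros(shape)
    inv_sharp[inv_seg] = inv_mean
    ck14_sharp = np.zeros(shape)
    ck14_sharp[ck14_seg] = ck14_mean

    stacks: dict[str, np.ndarray] = {}
    for name, sharp in (("involucrin", inv_sharp), ("ck14", ck14_sharp)):
        blurred = ndi.gaussian_filter(sharp, sigma=8.0)
        stack = np.empty((n_z, *shape), dtype=np.float64)
        for z in range(n_z):
            plane = sharp if z in focused else blurred
            stack[z] = plane
        if noise_sd > 0:
            stack = stack + rng.normal(0.0, noise_sd, size=stack.shape)
        stacks[name] = stack.astype(np.float32)

    truth = {
        "programmed_ratio": float(programmed_ratio),
        "focused_plane_indices": set(focused),
        "involucrin_segment_area_px": int(inv_seg.sum()),
        "ck14_segment_area_px": int(ck14_seg.sum()),
        "spheroid_area_px": int((rr <= R).sum()),
    }
    return stacks, truth
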