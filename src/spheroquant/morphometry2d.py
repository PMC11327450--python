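"""Brightfield spheroid morphometry.

Measures spheroid diameter and eccentricity from 2D brightfield images and
quantifies the percentage of image area covered by dissociated cells and
satellite aggregates around the main spheroid.  Diameter is the
equivalent-circle diameter derived from mask area; eccentricity comes from
the second central moments of the mask (the fitted-ellipse eccentricity).
The loose-cell measurement smooths with a Gaussian filter, thresholds with
Otsu's two-class method, and keeps objects whose equivalent diameter lies
in a 5–200 px band to exclude the core spheroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops


class EmptyMaskError(ValueError):
    """No foreground was found where an object was required."""


@dataclass(frozen=True)
class SpheroidMorphometry:
    """Size and shape of the main spheroid in one brightfield image."""

    diameter_um: float
    eccentricity: float
    area_um2: float
    centroid_px: tuple[float, float]


@dataclass(frozen=True)
class LooseCellResult:
    """Dissociated-cell quantification around the main spheroid.

    ``occupied_area_fraction`` is a percentage of the full image area.
    """

    occupied_area_fraction: float
    n_objects: int
    object_areas_px: tuple[int, ...]


def segment_main_spheroid(
    image: np.ndarray,
    *,
    smooth_sigma_px: float = 2.0,
    invert: bool = False,
) -> np.ndarray:
    """Segment the dominant spheroid as a binary mask.

    Expects a single dark object on a bright background (set ``invert`` for
    the opposite polarity).  The image is Gaussian-smoothed, thresholded
    into two classes with Otsu's method, hole-filled, and reduced to the
    largest connected component.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D image")
    smoothed = gaussian(img, sigma=smooth_sigma_px, preserve_range=True)
    t = threshold_otsu(smoothed)
    fg = smoothed > t if invert else smoothed < t
    if not fg.any():
        raise EmptyMaskError("no foreground found in image")
    fg = ndi.binary_fill_holes(fg)
    lbl, n = ndi.label(fg)
    sizes = np.bincount(lbl.ravel())[1:]
    return lbl == (int(np.argmax(sizes)) + 1)


def measure_diameter_eccentricity(
    mask: np.ndarray, pixel_size_um: float
) -> SpheroidMorphometry:
    """Equivalent-circle diameter and moment-based eccentricity of a mask.

    diameter_um = 2·sqrt(area_px/π)·pixel_size; eccentricity is that of the
    ellipse with matching second central moments, so it reproduces the
    analytic value for exact ellipse masks and is 0 for a circle.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("cannot measure an empty mask")
    if pixel_size_um <= 0:
        raise ValueError("pixel size must be positive")
    props = regionprops(mask.astype(np.uint8))[0]
    area_px = props.area
    return SpheroidMorphometry(
        diameter_um=2.0 * np.sqrt(area_px / np.pi) * pixel_size_um,
        eccentricity=float(props.eccentricity),
        area_um2=float(area_px) * pixel_size_um**2,
        centroid_px=tuple(props.centroid),
    )


def measure_loose_cell_area(
    image: np.ndarray,
    main_mask: np.ndarray,
    *,
    gaussian_sigma_px: float = 5.0,
    diameter_band_px: tuple[float, float] = (5.0, 200.0),
    invert: bool = False,
) -> LooseCellResult:
    """Percentage of image area occupied by dissociated cells.

    The image is smoothed with a Gaussian filter, thresholded with Otsu's
    two-class method, and objects overlapping ``main_mask`` are discarded.
    Remaining objects are kept when their equivalent-circle diameter lies
    within ``diameter_band_px`` (inclusive); the result is
    100 · kept pixel area / total image area.
    """
    lo, hi = diameter_band_px
    if lo > hi:
        raise ValueError(f"diameter band is inverted: {diameter_band_px}")
    img = np.asarray(image, dtype=float)
    if img.shape != np.asarray(main_mask).shape:
        raise ValueError("image and main_mask shapes differ")
    smoothed = gaussian(img, sigma=gaussian_sigma_px, preserve_range=True)
    t = threshold_otsu(smoothed)
    fg = smoothed > t if invert else smoothed < t

    lbl = sk_label(fg, connectivity=2)
    main = np.asarray(main_mask, dtype=bool)
    drop = np.unique(lbl[main])
    kept_areas: list[int] = []
    kept_mask = np.zeros(img.shape, dtype=bool)
    for p in regionprops(lbl):
        if p.label in drop:
            continue
        if lo <= p.equivalent_diameter_area <= hi:
            kept_areas.append(int(p.area))
            kept_mask[lbl == p.label] = True
    frac = 100.0 * kept_mask.sum() / kept_mask.size
    return LooseCellResult(
        occupied_area_fraction=float(frac),
        n_objects=len(kept_areas),
        object_areas_px=tuple(kept_areas),
    )
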