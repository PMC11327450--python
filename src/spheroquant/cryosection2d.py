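"""Cryosection differentiation quantification.

Quantifies epidermal differentiation from two-channel (Involucrin / CK14)
cryosection z-stacks: selects and sums the three most in-focus planes,
segments each channel after median filtering, and computes the ratio of
integrated densities.  Integrated density is the mean intensity inside a
channel's segment multiplied by the segment area normalised to the whole
spheroid area; the spheroid area itself is obtained automatically from the
Involucrin channel by thresholding, largest-component selection, closing
and hole filling.

Focus is scored per plane as the variance of a discrete Laplacian — a
standard, parameter-free sharpness measure; the selected planes need not
be adjacent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import disk


class EmptySegmentError(ValueError):
    """Thresholding produced no foreground where a segment was required."""


@dataclass(frozen=True)
class IntegratedDensity:
    """Mean intensity in a segment × its spheroid-normalised area."""

    channel_name: str
    mean_intensity_in_segment: float
    normalized_area: float
    integrated_density: float


def focus_scores(zstack: np.ndarray) -> np.ndarray:
    """Per-plane sharpness: variance of the discrete Laplacian."""
    stack = np.asarray(zstack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("expected a (z, y, x) stack")
    return np.array([ndi.laplace(p).var() for p in stack])


def select_focused_planes(zstack: np.ndarray, n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Sum the ``n`` most in-focus planes of a z-stack.

    Returns ``(summed_image, selected_indices)``; indices are sorted
    ascending.  Ties are broken toward lower plane index for determinism.
    """
    stack = np.asarray(zstack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("expected a (z, y, x) stack")
    if stack.shape[0] < n:
        raise ValueError(f"stack depth {stack.shape[0]} < n = {n}")
    scores = focus_scores(stack)
    # stable selection: sort by (-score, index)
    order = np.lexsort((np.arange(scores.size), -scores))
    idx = np.sort(order[:n])
    return stack[idx].sum(axis=0), idx


def segment_channel(image: np.ndarray, median_radius_px: int = 2) -> np.ndarray:
    """Binary channel segment: median filter then Otsu two-class threshold."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D image")
    filtered = ndi.median_filter(img, footprint=disk(median_radius_px))
    if np.ptp(filtered) == 0:
        raise EmptySegmentError("constant image: no threshold separates a segment")
    t = threshold_otsu(filtered)
    seg = filtered > t
    if not seg.any():
        raise EmptySegmentError("thresholding produced an empty segment")
    return seg


def spheroid_area_2d(reference_image: np.ndarray, median_radius_px: int = 2) -> int:
    """Whole-spheroid area in pixels from a reference channel image.

    Threshold → largest connected component → morphological closing → hole
    fill; replaces the manual whole-spheroid wand selection with an
    automated equivalent.
    """
    seg = segment_channel(reference_image, median_radius_px)
    lbl, n = ndi.label(seg)
    sizes = np.bincount(lbl.ravel())[1:]
    largest = lbl == (int(np.argmax(sizes)) + 1)
    closed = ndi.binary_closing(largest, structure=disk(5))
    filled = ndi.binary_fill_holes(closed)
    area = int(filled.sum())
    if area == 0:
        raise EmptySegmentError("no spheroid found in reference image")
    return area


def integrated_density(
    image: np.ndarray,
    segment: np.ndarray,
    spheroid_area_px: int,
    channel_name: str,
) -> IntegratedDensity:
    """Integrated density of one channel's segment.

    mean intensity inside the segment × (segment area / spheroid area).
    """
    if spheroid_area_px <= 0:
        raise ValueError("spheroid area must be positive")
    seg = np.asarray(segment, dtype=bool)
    if not seg.any():
        raise EmptySegmentError(f"empty segment for channel {channel_name!r}")
    mean = float(np.asarray(image, float)[seg].mean())
    norm_area = float(seg.sum()) / spheroid_area_px
    return IntegratedDensity(
        channel_name=channel_name,
        mean_intensity_in_segment=mean,
        normalized_area=norm_area,
        integrated_density=mean * norm_area,
    )


def differentiation_ratio(involucrin: IntegratedDensity, ck14: IntegratedDensity) -> float:
    """Involucrin / CK14 integrated-density ratio for one cryosection."""
    if ck14.integrated_density <= 0:
        raise ValueError("CK14 integrated density must be positive")
    return involucrin.integrated_density / ck14.integrated_density


def analyze_cryosection(
    involucrin_stack: np.ndarray,
    ck14_stack: np.ndarray,
    n_planes: int = 3,
    median_radius_px: int = 2,
) -> dict:
    """Full cryosection pipeline for one two-channel z-stack.

    Returns a dictionary with both channels' integrated densities, the
    differentiation ratio, and the selected focus planes per channel.
    """
    inv_img, inv_idx = select_focused_planes(involucrin_stack, n_planes)
    ck_img, ck_idx = select_focused_planes(ck14_stack, n_planes)
    area = spheroid_area_2d(inv_img, median_radius_px)
    inv_id = integrated_density(
        inv_img, segment_channel(inv_img, median_radius_px), area, "involucrin"
    )
    ck_id = integrated_density(
        ck_img, segment_channel(ck_img, median_radius_px), area, "ck14"
    )
    return {
        "involucrin": inv_id,
        "ck14": ck_id,
        "ratio": differentiation_ratio(inv_id, ck_id),
        "focused_planes_involucrin": inv_idx,
        "focused_planes_ck14": ck_idx,
        "spheroid_area_px": area,
    }
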