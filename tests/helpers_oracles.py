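"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: matching is scored by
explicit per-pair voxel masks, volumes by direct voxel counts, and the
morphological closing by chamfer distance transforms (n iterations of a
connectivity-1 dilation equal dilation by an L1 ball of radius n).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi


def crop_to_labels(*arrays: np.ndarray, pad: int = 1) -> list[np.ndarray]:
    """Crop all arrays to the joint nonzero bounding box of the first."""
    nz = np.argwhere(arrays[0] != 0)
    lo = np.maximum(nz.min(axis=0) - pad, 0)
    hi = nz.max(axis=0) + pad + 1
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    return [a[sl] for a in arrays]


def brute_force_matches(
    nuc: np.ndarray, cell: np.ndarray, threshold: float, metric: str
) -> list[tuple[int, int, float]]:
    """All-pairs overlap scoring with greedy one-to-one assignment.

    Returns accepted (cell_id, nucleus_id, score) triples sorted by cell id,
    using the same tie rules as the implementation: descending score, then
    ascending cell id, then ascending nucleus id.
    """
    pairs = []
    for n in np.unique(nuc[nuc > 0]):
        nm = nuc == n
        n_size = nm.sum()
        for c in np.unique(cell[cell > 0]):
            cm = cell == c
            inter = (nm & cm).sum()
            if inter == 0:
                continue
            if metric == "iou":
                score = inter / (n_size + cm.sum() - inter)
            else:
                score = inter / n_size
            pairs.append((float(score), int(c), int(n)))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_c, used_n, accepted = set(), set(), []
    for score, c, n in pairs:
        if score < threshold:
            break
        if c in used_c or n in used_n:
            continue
        used_c.add(c)
        used_n.add(n)
        accepted.append((c, n, score))
    return sorted(accepted)


def brute_force_survivors(
    labels: np.ndarray, voxel_volume: float, v_min: float, v_max: float
) -> set[int]:
    """Nuclei whose voxel-count volume lies inside the band, by direct scan."""
    out = set()
    for i in np.unique(labels[labels > 0]):
        vol = (labels == i).sum() * voxel_volume
        if v_min <= vol <= v_max:
            out.add(int(i))
    return out


def chamfer_closing(mask: np.ndarray, n: int) -> np.ndarray:
    """Closing by an L1 ball of radius n via taxicab distance transforms."""
    dilated = ndi.distance_transform_cdt(~mask, metric="taxicab") <= n
    return ndi.distance_transform_cdt(dilated, metric="taxicab") > n


def largest_component_filled(mask: np.ndarray) -> np.ndarray:
    filled = ndi.binary_fill_holes(mask)
    lbl, n = ndi.label(filled)
    if n <= 1:
        return filled
    sizes = np.bincount(lbl.ravel())[1:]
    return lbl == (int(np.argmax(sizes)) + 1)


def brute_force_ki67(
    ki67: np.ndarray, cell: np.ndarray, min_fraction: float
) -> set[int]:
    """Per-object majority-overlap assignment by explicit voxel tallies."""
    positive = set()
    for k in np.unique(ki67[ki67 > 0]):
        km = ki67 == k
        size = km.sum()
        best_c, best_frac = None, -1.0
        for c in np.unique(cell[km]):
            if c == 0:
                continue
            frac = (km & (cell == c)).sum() / size
            if frac > best_frac:
                best_c, best_frac = int(c), frac
        if best_c is not None and best_frac >= min_fraction:
            positive.add(best_c)
    return positive
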