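"""Subcellular compartment analysis: N/C intensity ratios per cell.

Associates nuclear instance masks with whole-cell (membrane) masks by
overlap scoring, derives cytoplasm masks by subtraction, computes
background-corrected mean intensities per compartment, the per-cell
nuclear-to-cytoplasmic (N/C) ratio, and per-cell Ki-67 status.

Overlap matching supports two scores: strict IoU (Jaccard,
|N∩C| / |N∪C|) and nucleus coverage (|N∩C| / |N|).  A nucleus is rarely
half the volume of its whole cell, so strict IoU against a minimum of 0.5
would reject essentially every true pair; the default score is therefore
nucleus coverage with the same 0.5 minimum, and strict IoU remains
available for sensitivity analysis.

Background is the mean intensity over all voxels outside the detected
cells; compartment means are the voxel-intensity sum divided by the voxel
count, background-subtracted before forming the ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volumes import IntensityVolume, LabeledVolume, check_same_grid

DEFAULT_OVERLAP_THRESHOLD = 0.5


@dataclass(frozen=True)
class CompartmentMatch:
    """Accepted nucleus-to-cell assignment with its overlap score."""

    cell_id: int
    nucleus_id: int
    overlap_score: float
    metric_name: str


@dataclass(frozen=True)
class CellIntensityRecord:
    """Background-corrected per-cell compartment intensities and N/C ratio."""

    cell_id: int
    mean_nuc: float
    mean_cyto: float
    background: float
    nc_ratio: float
    ki67_status: bool
    nuc_volume_um3: float
    cyto_volume_um3: float


def _overlap_table(
    a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Co-occurrence counts between two label volumes.

    Returns (a_ids, b_ids, counts) for every voxel-sharing (a, b) pair with
    both labels positive.
    """
    sel = (a > 0) & (b > 0)
    pairs = np.stack([a[sel], b[sel]])
    uniq, counts = np.unique(pairs, axis=1, return_counts=True)
    return uniq[0], uniq[1], counts


def match_nuclei_to_cells(
    nucleus_labels: LabeledVolume,
    cell_labels: LabeledVolume,
    threshold: float = DEFAULT_OVERLAP_THRESHOLD,
    metric: str = "nucleus_coverage",
) -> list[CompartmentMatch]:
    """Assign each nucleus to at most one cell by overlap score.

    Candidate (nucleus, cell) pairs are every pair sharing at least one
    voxel; the score is either strict ``iou`` or ``nucleus_coverage``.
    Pairs scoring below ``threshold`` are dropped; the rest are accepted
    greedily in order of descending score (ties broken by ascending cell
    id, then nucleus id) with one-to-one enforcement.
    """
    if metric not in ("iou", "nucleus_coverage"):
        raise ValueError(f"unknown overlap metric {metric!r}")
    check_same_grid(nucleus_labels, cell_labels)
    nuc, cell = nucleus_labels.data, cell_labels.data
    nuc_sizes = np.bincount(nuc.ravel())
    cell_sizes = np.bincount(cell.ravel())

    n_ids, c_ids, inter = _overlap_table(nuc, cell)
    if metric == "iou":
        union = nuc_sizes[n_ids] + cell_sizes[c_ids] - inter
        scores = inter / union
    else:
        scores = inter / nuc_sizes[n_ids]

    order = np.lexsort((n_ids, c_ids, -scores))
    taken_cells: set[int] = set()
    taken_nuclei: set[int] = set()
    matches: list[CompartmentMatch] = []
    for k in order:
        s = float(scores[k])
        if s < threshold:
            break
        ci, ni = int(c_ids[k]), int(n_ids[k])
        if ci in taken_cells or ni in taken_nuclei:
            continue
        taken_cells.add(ci)
        taken_nuclei.add(ni)
        matches.append(
            CompartmentMatch(cell_id=ci, nucleus_id=ni, overlap_score=s, metric_name=metric)
        )
    matches.sort(key=lambda m: m.cell_id)
    return matches


def derive_cytoplasm(
    cell_labels: LabeledVolume,
    nucleus_labels: LabeledVolume,
    matches: list[CompartmentMatch],
) -> LabeledVolume:
    """Cytoplasm masks by mask subtraction, carrying the cell ids.

    For each matched pair the cytoplasm is the cell's voxels minus its
    matched nucleus's voxels; unmatched cells produce no cytoplasm label
    and are excluded from downstream intensity records.
    """
    check_same_grid(cell_labels, nucleus_labels)
    cell, nuc = cell_labels.data, nucleus_labels.data
    matched_cells = np.array([m.cell_id for m in matches], dtype=cell.dtype)
    nuc_of_cell = np.zeros(int(cell.max()) + 1, dtype=nuc.dtype)
    for m in matches:
        nuc_of_cell[m.cell_id] = m.nucleus_id

    cyto = np.where(np.isin(cell, matched_cells), cell, 0)
    # remove each cell's own nucleus voxels
    cyto[(nuc > 0) & (nuc_of_cell[cyto] == nuc)] = 0
    return LabeledVolume(cyto.astype(cell.dtype), cell_labels.spacing_um)


def background_level(
    intensity: IntensityVolume, cell_labels: LabeledVolume, statistic: str = "mean"
) -> float:
    """Intensity background: mean over all voxels outside the detected cells."""
    check_same_grid(intensity, cell_labels)
    outside = cell_labels.data == 0
    if not outside.any():
        raise ValueError("no background voxels: cells cover the whole volume")
    vals = intensity.data[outside]
    if statistic == "mean":
        return float(vals.mean())
    if statistic == "median":
        return float(np.median(vals))
    raise ValueError(f"unknown background statistic {statistic!r}")


def compartment_means_and_ratio(
    intensity: IntensityVolume,
    nucleus_labels: LabeledVolume,
    cytoplasm_labels: LabeledVolume,
    matches: list[CompartmentMatch],
    background: float,
    ki67_positive_cells: set[int] | None = None,
) -> tuple[list[CellIntensityRecord], dict[str, int]]:
    """Per-cell background-corrected compartment means and N/C ratios.

    The mean per compartment is the voxel-intensity sum divided by the
    voxel count; ``background`` is subtracted from both means and the N/C
    ratio is mean_nuc / mean_cyto on the corrected values.  Cells with an
    empty cytoplasm or a non-positive corrected cytoplasmic mean are
    excluded and tallied in the returned QC dictionary.
    """
    check_same_grid(intensity, nucleus_labels, cytoplasm_labels)
    img = intensity.data.astype(np.float64)
    vox = nucleus_labels.voxel_volume_um3
    ki67_positive_cells = ki67_positive_cells or set()

    nuc, cyto = nucleus_labels.data, cytoplasm_labels.data
    n_max = int(max(nuc.max(), cyto.max())) + 1
    nuc_sum = np.bincount(nuc.ravel(), weights=img.ravel(), minlength=n_max)
    nuc_cnt = np.bincount(nuc.ravel(), minlength=n_max)
    cyto_sum = np.bincount(cyto.ravel(), weights=img.ravel(), minlength=n_max)
    cyto_cnt = np.bincount(cyto.ravel(), minlength=n_max)

    records: list[CellIntensityRecord] = []
    qc = {"empty_cytoplasm": 0, "nonpositive_cyto_mean": 0}
    for m in sorted(matches, key=lambda m: m.cell_id):
        ci, ni = m.cell_id, m.nucleus_id
        if cyto_cnt[ci] == 0:
            qc["empty_cytoplasm"] += 1
            continue
        mean_nuc = nuc_sum[ni] / nuc_cnt[ni] - background
        mean_cyto = cyto_sum[ci] / cyto_cnt[ci] - background
        if mean_cyto <= 0:
            qc["nonpositive_cyto_mean"] += 1
            continue
        records.append(
            CellIntensityRecord(
                cell_id=ci,
                mean_nuc=float(mean_nuc),
                mean_cyto=float(mean_cyto),
                background=float(background),
                nc_ratio=float(mean_nuc / mean_cyto),
                ki67_status=ci in ki67_positive_cells,
                nuc_volume_um3=float(nuc_cnt[ni] * vox),
                cyto_volume_um3=float(cyto_cnt[ci] * vox),
            )
        )
    return records, qc


def assign_ki67(
    ki67_labels: LabeledVolume,
    cell_labels: LabeledVolume,
    min_object_fraction: float = 0.5,
) -> set[int]:
    """Cells positive for Ki-67, by majority overlap of Ki-67 objects.

    Each Ki-67 object is assigned to the cell containing the largest
    fraction of its voxels, provided that fraction is at least
    ``min_object_fraction``; a cell is Ki-67+ when at least one object is
    assigned to it.
    """
    check_same_grid(ki67_labels, cell_labels)
    k_ids, c_ids, inter = _overlap_table(ki67_labels.data, cell_labels.data)
    if k_ids.size == 0:
        return set()
    k_sizes = np.bincount(ki67_labels.data.ravel())
    fracs = inter / k_sizes[k_ids]

    positive: set[int] = set()
    for k in np.unique(k_ids):
        sel = k_ids == k
        best = np.argmax(fracs[sel])
        if fracs[sel][best] >= min_object_fraction:
            positive.add(int(c_ids[sel][best]))
    return positive


def records_to_frame(records: list[CellIntensityRecord]) -> pd.DataFrame:
    """Per-cell records as a tidy table, one row per included cell."""
    return pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in records],
            "mean_nuc": [r.mean_nuc for r in records],
            "mean_cyto": [r.mean_cyto for r in records],
            "background": [r.background for r in records],
            "nc_ratio": [r.nc_ratio for r in records],
            "ki67_status": [r.ki67_status for r in records],
            "nuc_volume_um3": [r.nuc_volume_um3 for r in records],
            "cyto_volume_um3": [r.cyto_volume_um3 for r in records],
        }
    )
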