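"""Spatial radial profiling of cells inside a spheroid.

Builds a convex hull around the centroids of all identified cells — the
hull outlines the outer boundary of the cellular distribution — and, for
each cell, casts a ray from the hull centre through the cell's centroid to
its intersection with the hull surface.  The Euclidean distance from that
intersection point to the centroid is the cell's distance to the spheroid
rim, which is then joined with N/C ratio and Ki-67 status for radial
profiles.

The hull centre is the volume centroid of the hull polyhedron (robust to
uneven surface-point density); the mean of all centroids is available as
an alternative.  The ray-surface intersection is computed exactly from the
hull's supporting half-spaces: along the outward ray the exit parameter is
the smallest positive boundary crossing over all face planes, which for a
convex polytope is the unique surface intersection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError


class DegenerateHullError(ValueError):
    """Centroids are coplanar/collinear and define no 3D hull."""


@dataclass(frozen=True)
class HullModel:
    """Convex hull of cell centroids with its volume centroid."""

    vertices: np.ndarray  # (n_vertices, 3) points, µm
    faces: np.ndarray  # (n_faces, 3) vertex index triplets
    center: np.ndarray  # (3,) volume centroid, µm
    equations: np.ndarray  # (n_faces, 4) outward face planes [n | d], n·x + d <= 0 inside


@dataclass(frozen=True)
class SpatialRecord:
    cell_id: int
    distance_to_hull_um: float
    centroid_um: tuple[float, float, float]
    nc_ratio: float
    ki67_status: bool


def build_hull(centroids: np.ndarray, center: str = "volume_centroid") -> HullModel:
    """Convex hull around cell centroids.

    ``center`` selects the hull centre definition: the polyhedron's
    ``volume_centroid`` (default) or the plain ``centroid_mean`` of all
    input points.  Requires at least 4 non-coplanar points.
    """
    pts = np.asarray(centroids, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 4:
        raise DegenerateHullError("need at least 4 three-dimensional points")
    try:
        hull = ConvexHull(pts)
    except QhullError as e:
        raise DegenerateHullError(f"degenerate centroid cloud: {e}") from e

    verts = pts[hull.vertices]
    if center == "volume_centroid":
        ctr = _polyhedron_volume_centroid(pts, hull.simplices)
    elif center == "centroid_mean":
        ctr = pts.mean(axis=0)
    else:
        raise ValueError(f"unknown hull centre definition {center!r}")
    return HullModel(
        vertices=verts,
        faces=hull.simplices.copy(),
        center=ctr,
        equations=hull.equations.copy(),
    )


def _polyhedron_volume_centroid(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Volume centroid via tetrahedra against an interior reference point.

    Qhull facet vertex order is not consistently oriented, so unsigned
    volumes are used; the reference point is interior to the convex hull,
    hence the facet tetrahedra tile the polyhedron without overlap and the
    unsigned decomposition is exact.
    """
    ref = points[simplices].reshape(-1, 3).mean(axis=0)
    a = points[simplices[:, 0]] - ref
    b = points[simplices[:, 1]] - ref
    c = points[simplices[:, 2]] - ref
    vols = np.abs(np.einsum("ij,ij->i", a, np.cross(b, c))) / 6.0
    cents = ref + (a + b + c) / 4.0
    return (cents * vols[:, None]).sum(axis=0) / vols.sum()


def distance_to_hull(hull: HullModel, centroid: np.ndarray) -> float:
    """Ray-intersection distance from a cell centroid to the hull surface.

    Casts the ray from the hull centre through the centroid and intersects
    it with the hull boundary on the outward side; returns the Euclidean
    distance from the intersection point to the centroid.  A centroid
    coincident with the centre has no ray direction; the minimum
    centre-to-face distance is returned instead.  Centroids marginally
    outside the hull (floating error) are clamped to distance 0.
    """
    p = np.asarray(centroid, dtype=float)
    normals = hull.equations[:, :3]
    offsets = hull.equations[:, 3]
    d = p - hull.center
    norm = np.linalg.norm(d)
    scale = np.abs(hull.vertices).max() + 1.0
    if norm < 1e-12 * scale:
        import warnings

        warnings.warn("centroid coincides with hull centre; using min face distance")
        return float(np.min(-(normals @ hull.center + offsets)))

    # exit parameter: smallest positive t with n·(c + t·d) + off = 0, n·d > 0
    denom = normals @ d
    numer = -(normals @ hull.center + offsets)  # distance margin of the centre, > 0
    with np.errstate(divide="ignore"):
        t = np.where(denom > 1e-15, numer / denom, np.inf)
    t_exit = float(t.min())
    exit_point = hull.center + t_exit * d
    dist = float(np.linalg.norm(exit_point - p))
    # centroid beyond the surface (outside the hull) ⇒ clamp to the surface
    if t_exit < 1.0:
        return 0.0
    return dist


def distances_to_hull(hull: HullModel, centroids: np.ndarray) -> np.ndarray:
    """Vector of per-cell ray-intersection distances to the hull surface."""
    return np.array([distance_to_hull(hull, c) for c in np.asarray(centroids, float)])


def radial_profile(records: pd.DataFrame, n_bins: int) -> pd.DataFrame:
    """Bin cells by distance to hull and aggregate N/C ratio and Ki-67.

    ``records`` needs columns distance_to_hull_um, nc_ratio, ki67_status.
    Bins are equal-width over [0, max distance]; empty bins are reported
    with n = 0 and NaN aggregates.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be at least 1")
    if len(records) == 0:
        raise ValueError("need at least one record")
    d = records["distance_to_hull_um"].to_numpy(float)
    edges = np.linspace(0.0, max(d.max(), np.finfo(float).tiny), n_bins + 1)
    idx = np.clip(np.digitize(d, edges[1:-1]), 0, n_bins - 1)

    rows = []
    for b in range(n_bins):
        sel = idx == b
        sub = records.loc[sel]
        rows.append(
            {
                "bin_center_um": (edges[b] + edges[b + 1]) / 2.0,
                "mean_nc_ratio": sub["nc_ratio"].mean() if sel.any() else np.nan,
                "median_nc_ratio": sub["nc_ratio"].median() if sel.any() else np.nan,
                "ki67_positive_fraction": sub["ki67_status"].mean() if sel.any() else np.nan,
                "n": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows)


def scatter_matrix_figure(records: pd.DataFrame, path: str) -> None:
    """Scatter-matrix of per-cell properties, coloured by Ki-67 status."""
    import matplotlib

    matplotlib.use("Agg")
    import seaborn as sns

    cols = [c for c in ("distance_to_hull_um", "nc_ratio", "nuc_volume_um3") if c in records]
    g = sns.pairplot(
        records,
        vars=cols,
        hue="ki67_status" if "ki67_status" in records else None,
        corner=True,
        plot_kws={"s": 12, "alpha": 0.6},
    )
    g.savefig(path, dpi=120)
    import matplotlib.pyplot as plt

    plt.close("all")
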