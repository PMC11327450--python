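"""Volume I/O, run configuration, and the end-to-end pipeline.

Volumes are stored as multi-page TIFF with the physical voxel spacing and
payload kind embedded as JSON in the image description tag, so a written
volume round-trips spacing-exact.  Tables are CSV with a units-bearing
header.  ``run_all`` ties generator → volumetrics → subcellular → spatial
into one reproducible run and writes a manifest of content checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .volumes import DEFAULT_SPACING_UM, IntensityVolume, LabeledVolume

logger = logging.getLogger("spheroquant")


# ---------------------------------------------------------------------------
# volume I/O
# ---------------------------------------------------------------------------


def write_volume(path: str | Path, volume: LabeledVolume | IntensityVolume) -> Path:
    """Write a volume as multi-page TIFF with spacing metadata."""
    path = Path(path)
    kind = "labels" if isinstance(volume, LabeledVolume) else "intensity"
    desc = json.dumps({"spacing_um": list(volume.spacing_um), "kind": kind})
    data = volume.data
    if kind == "intensity":
        data = np.asarray(data, dtype=np.float32)  # storage precision
    tifffile.imwrite(path, data, description=desc, photometric="minisblack")
    return path


def read_volume(
    path: str | Path,
    expect: str,
    spacing_um: tuple[float, float, float] | None = None,
) -> LabeledVolume | IntensityVolume:
    """Read a TIFF volume as labels or intensity.

    ``expect`` is ``"labels"`` or ``"intensity"``.  Spacing comes from the
    embedded metadata (JSON image description, or ImageJ spacing plus the
    resolution tags) unless overridden; label volumes must hold integers.
    """
    if expect not in ("labels", "intensity"):
        raise ValueError(f"expect must be 'labels' or 'intensity', got {expect!r}")
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta_spacing = _spacing_from_tiff(tf)
    if data.ndim == 2:
        data = data[None]
    spacing = spacing_um or meta_spacing
    if spacing is None:
        raise ValueError(
            f"{path}: no voxel spacing in metadata; pass an explicit spacing"
        )
    if expect == "labels":
        if not np.issubdtype(data.dtype, np.integer):
            raise TypeError(
                f"{path}: label volume must hold integers, found {data.dtype}"
            )
        return LabeledVolume(data, tuple(spacing))
    return IntensityVolume(np.asarray(data, dtype=np.float32), tuple(spacing))


def _spacing_from_tiff(tf: tifffile.TiffFile) -> tuple[float, float, float] | None:
    page = tf.pages[0]
    desc = page.description or ""
    try:
        meta = json.loads(desc)
        if "spacing_um" in meta:
            return tuple(float(s) for s in meta["spacing_um"])
    except (json.JSONDecodeError, TypeError):
        pass
    if tf.imagej_metadata and "spacing" in tf.imagej_metadata:
        z = float(tf.imagej_metadata["spacing"])
        res = page.tags.get("XResolution")
        if res is not None:
            num, den = res.value
            xy = den / num if num else 1.0
            return (z, xy, xy)
    return None


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Full parameterisation of an end-to-end synthetic pipeline run."""

    seed: int = 0
    out_dir: str = "run_out"
    spacing_um: tuple[float, float, float] = DEFAULT_SPACING_UM
    # generator
    spheroid_radius_um: float = 60.0
    n_cells: int = 200
    cell_radius_um_mean: float = 6.0
    cell_radius_um_sd: float = 0.5
    nucleus_volume_fraction: float = 0.5
    ki67_fraction: float = 0.3
    nc_ratio_center: float = 1.0
    nc_ratio_rim: float = 2.0
    background_level: float = 10.0
    noise_sd: float = 5.0
    blur_sigma_vox: float = 1.0
    # volumetrics
    v_min_um3: float = 300.0
    v_max_um3: float = 3000.0
    closing_iterations: int = 40
    # subcellular
    overlap_threshold: float = 0.5
    overlap_metric: str = "nucleus_coverage"
    # spatial
    n_bins: int = 10
    write_figures: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "spacing_um" in raw:
            raw["spacing_um"] = tuple(raw["spacing_um"])
        return cls(**raw)

    def _serializable(self) -> dict:
        # out_dir is self-referential (the directory the copy sits in) and
        # must not perturb reproducibility hashes
        d = dataclasses.asdict(self)
        d["spacing_um"] = list(d["spacing_um"])
        d.pop("out_dir")
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self._serializable(), sort_keys=True))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self._serializable(), sort_keys=True).encode()
        ).hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    version: str
    config_hash: str
    checksums: dict[str, str]
    timestamps: dict[str, str] = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# end-to-end orchestration
# ---------------------------------------------------------------------------


def run_all(config: RunConfig) -> RunManifest:
    """Run generator → volumetrics → subcellular → spatial, write outputs.

    Stages execute in dependency order; a stage failure aborts with the
    stage name while earlier outputs stay on disk.  The manifest (written
    last) records the config hash and a SHA-256 checksum of every output
    file; identical configs reproduce identical checksums.
    """
    from . import spatial, subcellular, synthetic, volumetrics3d

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    written: list[Path] = [out / "config.yaml"]
    timestamps: dict[str, str] = {}

    def _stage(name):
        logger.info("stage %s: starting", name)
        timestamps[name] = time.strftime("%Y-%m-%dT%H:%M:%S")

    try:
        _stage("synthetic")
        spec = synthetic.SyntheticSpec3D(
            seed=config.seed,
            voxel_spacing_um=config.spacing_um,
            spheroid_radius_um=config.spheroid_radius_um,
            n_cells=config.n_cells,
            cell_radius_um_mean=config.cell_radius_um_mean,
            cell_radius_um_sd=config.cell_radius_um_sd,
            nucleus_volume_fraction=config.nucleus_volume_fraction,
            ki67_fraction=config.ki67_fraction,
            nc_ratio_center=config.nc_ratio_center,
            nc_ratio_rim=config.nc_ratio_rim,
            background_level=config.background_level,
            noise_sd=config.noise_sd,
            blur_sigma_vox=config.blur_sigma_vox,
        )
        sph = synthetic.generate_spheroid(spec)
        for name, vol in (
            ("cell_labels", sph.cell_labels),
            ("nucleus_labels", sph.nucleus_labels),
            ("ki67_labels", sph.ki67_labels),
        ):
            written.append(write_volume(out / f"{name}.tif", vol))
        for name, ch in sph.channels.items():
            written.append(write_volume(out / f"channel_{name}.tif", ch))
        sph.truth.to_csv(out / "truth.csv", index=False)
        written.append(out / "truth.csv")
    except Exception as e:
        raise RuntimeError(f"stage 'synthetic' failed: {e}") from e

    try:
        _stage("volumetrics3d")
        filtered, nuc_records = volumetrics3d.filter_nuclei(
            sph.nucleus_labels, config.v_min_um3, config.v_max_um3
        )
        mask = volumetrics3d.reconstruct_spheroid_mask(
            filtered, n_iterations=config.closing_iterations
        )
        vol = volumetrics3d.compute_density_and_void(mask, filtered)
        written.append(
            write_volume(
                out / "spheroid_mask.tif",
                LabeledVolume(mask.astype(np.int32), config.spacing_um),
            )
        )
    except Exception as e:
        raise RuntimeError(f"stage 'volumetrics3d' failed: {e}") from e

    try:
        _stage("subcellular")
        matches = subcellular.match_nuclei_to_cells(
            filtered,
            sph.cell_labels,
            threshold=config.overlap_threshold,
            metric=config.overlap_metric,
        )
        cyto = subcellular.derive_cytoplasm(sph.cell_labels, filtered, matches)
        bg = subcellular.background_level(sph.channels["yap"], sph.cell_labels)
        ki67_pos = subcellular.assign_ki67(sph.ki67_labels, sph.cell_labels)
        records, qc = subcellular.compartment_means_and_ratio(
            sph.channels["yap"], filtered, cyto, matches, bg, ki67_pos
        )
        cells = subcellular.records_to_frame(records)
        written.append(write_volume(out / "cytoplasm_labels.tif", cyto))
        cells.to_csv(out / "cells.csv", index=False)
        written.append(out / "cells.csv")
        pct = volumetrics3d.ki67_fraction(len(ki67_pos), len(nuc_records))
        summary = pd.DataFrame(
            [
                {
                    "spheroid_volume_um3": vol.volume_um3,
                    "n_nuclei_inside": vol.n_nuclei_inside,
                    "density_per_um3": vol.density_per_um3,
                    "density_per_1e5_um3": vol.density_per_um3 * 1e5,
                    "void_volume_um3": vol.void_volume_um3,
                    "ki67_positive_pct": pct,
                    "qc_empty_cytoplasm": qc["empty_cytoplasm"],
                    "qc_nonpositive_cyto_mean": qc["nonpositive_cyto_mean"],
                }
            ]
        )
        summary.to_csv(out / "volumetrics.csv", index=False)
        written.append(out / "volumetrics.csv")
    except Exception as e:
        raise RuntimeError(f"stage 'subcellular' failed: {e}") from e

    try:
        _stage("spatial")
        cents = sph.cell_labels.centroids_um()
        all_pts = np.array([cents[i] for i in sorted(cents)])
        hull = spatial.build_hull(all_pts)
        cell_pts = {i: cents[i] for i in cells["cell_id"]}
        dists = spatial.distances_to_hull(
            hull, np.array([cell_pts[i] for i in cells["cell_id"]])
        )
        table = cells.assign(
            distance_to_hull_um=dists,
            centroid_z_um=[cell_pts[i][0] for i in cells["cell_id"]],
            centroid_y_um=[cell_pts[i][1] for i in cells["cell_id"]],
            centroid_x_um=[cell_pts[i][2] for i in cells["cell_id"]],
        )
        table.to_csv(out / "cells_spatial.csv", index=False)
        written.append(out / "cells_spatial.csv")
        profile = spatial.radial_profile(table, config.n_bins)
        profile.to_csv(out / "radial_profile.csv", index=False)
        written.append(out / "radial_profile.csv")
        if config.write_figures:
            spatial.scatter_matrix_figure(table, str(out / "scatter_matrix.png"))
    except Exception as e:
        raise RuntimeError(f"stage 'spatial' failed: {e}") from e

    manifest = RunManifest(
        version=__version__,
        config_hash=config.config_hash(),
        checksums={p.name: _sha256(p) for p in sorted(set(written))},
        timestamps=timestamps,
    )
    manifest.write(out / "manifest.json")
    logger.info("run complete: %d files in %s", len(written), out)
    return manifest
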