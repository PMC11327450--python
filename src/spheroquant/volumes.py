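"""Core in-memory containers for 3D label and intensity volumes.

All volumes are (z, y, x) ordered numpy arrays carrying an anisotropic
physical voxel spacing in micrometres.  Label volumes are integer instance
masks where 0 is background and each positive id is one object; intensity
volumes are scalar fluorescence images sharing a label volume's grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: default confocal voxel spacing in µm (z, y, x): 1 µm z-step, 473 nm pixels
DEFAULT_SPACING_UM: tuple[float, float, float] = (1.0, 0.473, 0.473)


@dataclass(frozen=True)
class LabeledVolume:
    """3D integer instance-label image with physical voxel spacing.

    Parameters
    ----------
    data
        Integer array of shape (z, y, x); 0 is background.
    spacing_um
        Physical voxel size (z, y, x) in micrometres.
    """

    data: np.ndarray
    spacing_um: tuple[float, float, float] = DEFAULT_SPACING_UM

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError(f"label volume must be 3D, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise TypeError(f"label volume must hold integers, got {self.data.dtype}")
        if len(self.spacing_um) != 3 or any(s <= 0 for s in self.spacing_um):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing_um}")

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing_um))

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def ids(self) -> np.ndarray:
        """Sorted positive label ids present in the volume."""
        u = np.unique(self.data)
        return u[u > 0]

    def volumes_um3(self) -> dict[int, float]:
        """Per-label physical volume: voxel count × voxel volume."""
        counts = np.bincount(self.data.ravel())
        return {
            int(i): float(counts[i]) * self.voxel_volume_um3
            for i in range(1, counts.size)
            if counts[i] > 0
        }

    def centroids_um(self) -> dict[int, np.ndarray]:
        """Per-label centroid in physical (z, y, x) micrometre coordinates."""
        from scipy import ndimage as ndi

        ids = self.ids()
        if ids.size == 0:
            return {}
        coms = ndi.center_of_mass(self.data > 0, self.data, ids)
        spacing = np.asarray(self.spacing_um)
        return {int(i): np.asarray(c) * spacing for i, c in zip(ids, coms)}


@dataclass(frozen=True)
class IntensityVolume:
    """3D scalar fluorescence image on the same grid as a LabeledVolume."""

    data: np.ndarray
    spacing_um: tuple[float, float, float] = DEFAULT_SPACING_UM

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError(f"intensity volume must be 3D, got shape {self.data.shape}")
        if len(self.spacing_um) != 3 or any(s <= 0 for s in self.spacing_um):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing_um}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


def check_same_grid(*volumes: LabeledVolume | IntensityVolume) -> None:
    """Raise if the volumes do not share shape and spacing."""
    ref = volumes[0]
    for v in volumes[1:]:
        if v.data.shape != ref.data.shape:
            raise ValueError(f"grid mismatch: shapes {ref.data.shape} vs {v.data.shape}")
        if not np.allclose(v.spacing_um, ref.spacing_um):
            raise ValueError(f"grid mismatch: spacings {ref.spacing_um} vs {v.spacing_um}")
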