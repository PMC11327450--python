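import numpy as np
import pytest

from spheroquant import synthetic


@pytest.fixture(scope="session")
def clean_spec():
    """Small spheroid with no imaging degradation: exact-recovery regime."""
    return synthetic.SyntheticSpec3D(
        seed=11,
        spheroid_radius_um=30.0,
        n_cells=25,
        cell_radius_um_mean=6.0,
        cell_radius_um_sd=0.4,
        blur_sigma_vox=0.0,
        noise_sd=0.0,
        background_level=10.0,
    )


@pytest.fixture(scope="session")
def clean_spheroid(clean_spec):
    return synthetic.generate_spheroid(clean_spec)


@pytest.fixture(scope="session")
def degraded_spheroid():
    """Default study conditions: 200 cells, blur σ=1 voxel, 5% noise."""
    return synthetic.generate_spheroid(synthetic.SyntheticSpec3D(seed=42))


@pytest.fixture(scope="session")
def packed_128_nuclei():
    """Packed ellipsoidal nuclei centred in a 128³ grid (isotropic spacing).

    Centres stay within radius 20 of the volume centre so that 40 dilation
    iterations never reach the array faces.
    """
    from spheroquant.volumes import LabeledVolume

    rng = np.random.default_rng(7)
    shape = (128, 128, 128)
    labels = np.zeros(shape, dtype=np.int32)
    zz, yy, xx = np.mgrid[0:128, 0:128, 0:128].astype(float)
    centers = []
    label = 0
    attempts = 0
    while label < 40 and attempts < 4000:
        attempts += 1
        c = rng.uniform(-15, 15, 3) + 63.5
        if any(np.linalg.norm(c - c0) < 6.5 for c0 in centers):
            continue
        if np.linalg.norm(c - 63.5) > 15:
            continue
        label += 1
        ax = rng.uniform(2.5, 3.5, 3)
        inside = (
            ((zz - c[0]) / ax[0]) ** 2
            + ((yy - c[1]) / ax[1]) ** 2
            + ((xx - c[2]) / ax[2]) ** 2
        ) <= 1.0
        labels[inside] = label
        centers.append(c)
    assert label >= 20
    return LabeledVolume(labels, (1.0, 1.0, 1.0))
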