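"""Shared fixtures: small ground-truthed synthetic scenes and tables."""

import numpy as np
import pytest

from symbiolipo import ImageGroundTruth, PlantedBody, TableGroundTruth, generate_image

# Geometry for recovery tests: realistic in-plane pixel size, finer z-step so
# a ~2 µm body spans enough slices for its volume to be well sampled.
RECOVERY_SHAPE = (16, 128, 128)
RECOVERY_VOXEL = (135.0 / 512.0, 135.0 / 512.0, 0.5)  # (x, y, z) µm


def five_body_truth(noise_sd: float = 0.0, with_inclusion: bool = False) -> ImageGroundTruth:
    """Five well-separated lipid bodies (no skirt overlap), optional inclusion
    body that violates the default area cut-off."""
    spots = [(10.5, 10.5), (10.5, 23.3), (23.3, 10.5), (23.3, 23.3), (16.9, 16.9)]
    ratios = [0.8, 1.2, 1.6, 2.0, 2.5]
    peaks = [800.0, 1000.0, 900.0, 1100.0, 950.0]
    bodies = [
        PlantedBody(center_um=(4.0, y, x), radius_um=2.0, true_ratio=r, peak_reduced_intensity=p)
        for (y, x), r, p in zip(spots, ratios, peaks)
    ]
    shape = RECOVERY_SHAPE
    if with_inclusion:
        shape = (24, 128, 128)  # tall enough for the big body's 3-sigma support
        bodies.append(
            PlantedBody(
                center_um=(6.0, 16.9, 9.4),
                radius_um=3.6,  # summed in-plane area far above the 20 µm² cut-off
                true_ratio=1.5,
                peak_reduced_intensity=2000.0,
                is_inclusion_body=True,
            )
        )
    return ImageGroundTruth(
        bodies=bodies,
        shape=shape,
        voxel_size_um=RECOVERY_VOXEL,
        gaussian_noise_sd=noise_sd,
        poisson_noise=noise_sd > 0,
        chlorophyll_level=5.0,
    )


@pytest.fixture(scope="session")
def recovery_truth() -> ImageGroundTruth:
    return five_body_truth()


@pytest.fixture(scope="session")
def recovery_stack(recovery_truth):
    return generate_image(recovery_truth, seed=11)


@pytest.fixture(scope="session")
def default_table_truth() -> TableGroundTruth:
    return TableGroundTruth()


def three_blob_points(seed: int, n_per: int = 40) -> np.ndarray:
    """Three clearly separated isotropic blobs in the relative feature plane."""
    rng = np.random.default_rng(seed)
    centres = [(1.0, 1.0), (3.0, 0.5), (6.0, 0.4)]
    return np.vstack([rng.normal(c, 0.12, size=(n_per, 2)) for c in centres])
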