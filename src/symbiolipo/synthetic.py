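"""Synthetic confocal stacks and per-cell tables with known ground truth.

Two generators make every downstream stage testable without microscope data:

* :func:`generate_image` renders a two-lipid-channel (plus chlorophyll)
  z-stack containing planted lipid bodies of known position, size,
  oxidised/reduced ratio and brightness, with optional confocal-style noise
  (Poisson shot noise then additive Gaussian read noise). Bodies are smooth
  isotropic Gaussian blobs (sigma = radius/2, truncated at 3 sigma) — a
  PSF-like profile whose footprint above any detection threshold has a closed
  form, so recovery oracles can compute exactly what a detector should see.

* :func:`generate_cell_table` draws per-cell (lipid volume, LPO ratio) pairs
  from a three-component bivariate Gaussian mixture with species/colony
  structure, emulating the three metabolic profiles (endosymbiotic-like,
  transition, ex-symbiotic-like) the pipeline is meant to recover. Cell type
  is Bernoulli in each component's endosymbiont mix probability; colony
  random effects are additive on log lipid volume (volumes are positive and
  right-skewed) and on the raw LPO ratio.

Default image geometry follows the acquisition setup the pipeline targets:
512 x 512 px spanning 135 x 135 µm in-plane, ~1.0 µm z-slices.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .stack import ConfocalStack, VoxelSize

DEFAULT_SHAPE = (15, 512, 512)  # (z, y, x)
DEFAULT_PIXEL_UM = 135.0 / 512.0
DEFAULT_Z_STEP_UM = 1.0

#: Floor applied to non-positive generated lipid volumes (µm³).
VOLUME_FLOOR_UM3 = 1e-3

CELL_TYPES = ("endosymbiotic", "ex-symbiotic", "expelled")


# --------------------------------------------------------------------------
# image ground truth
# --------------------------------------------------------------------------


@dataclass
class PlantedBody:
    """One planted blob: a lipid body or (if flagged) an inclusion body.

    ``center_um`` is the physical (z, y, x) position in µm; ``true_ratio``
    is the latent oxidised/reduced intensity ratio the pipeline estimates.
    """

    center_um: tuple[float, float, float]
    radius_um: float
    true_ratio: float
    peak_reduced_intensity: float
    is_inclusion_body: bool = False

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("radius_um must be positive")
        if self.true_ratio < 0:
            raise ValueError("true_ratio must be >= 0")
        if self.peak_reduced_intensity <= 0:
            raise ValueError("peak_reduced_intensity must be positive")

    @property
    def sigma_um(self) -> float:
        """Gaussian profile width; the blob is truncated at 3 sigma."""
        return self.radius_um / 2.0

    @property
    def peak_combined(self) -> float:
        """Peak of the summed lipid channels, the detection signal."""
        return self.peak_reduced_intensity * (1.0 + self.true_ratio)

    def isophote_radius_um(self, threshold: float) -> float:
        """Radius at which the combined signal crosses ``threshold``.

        Returns 0 if the threshold is at or above the peak; the truncation
        radius (3 sigma) if the threshold lies below the truncated skirt.
        """
        if threshold >= self.peak_combined:
            return 0.0
        if threshold <= 0:
            return 3.0 * self.sigma_um
        r = self.sigma_um * math.sqrt(2.0 * math.log(self.peak_combined / threshold))
        return min(r, 3.0 * self.sigma_um)

    def expected_volume_um3(self, threshold: float) -> float:
        """Volume of the sphere enclosed by the ``threshold`` isophote."""
        r = self.isophote_radius_um(threshold)
        return 4.0 / 3.0 * math.pi * r**3


@dataclass
class ImageGroundTruth:
    """Planted parameters of one synthetic stack.

    The cell is a disk in-plane (``cell_center_um``/``cell_radius_um`` in
    (y, x) µm) applied to every slice, mirroring hand-drawn cell masks.
    """

    bodies: list[PlantedBody] = field(default_factory=list)
    shape: tuple[int, int, int] = DEFAULT_SHAPE
    voxel_size_um: tuple[float, float, float] = (
        DEFAULT_PIXEL_UM,
        DEFAULT_PIXEL_UM,
        DEFAULT_Z_STEP_UM,
    )  # (x, y, z)
    cell_center_um: tuple[float, float] | None = None  # (y, x); default: image centre
    cell_radius_um: float | None = None
    gaussian_noise_sd: float = 0.0
    poisson_noise: bool = False
    chlorophyll_level: float = 0.0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")
        ny_um = self.shape[1] * self.voxel_size_um[1]
        nx_um = self.shape[2] * self.voxel_size_um[0]
        if self.cell_center_um is None:
            self.cell_center_um = (ny_um / 2.0, nx_um / 2.0)
        if self.cell_radius_um is None:
            self.cell_radius_um = 0.45 * min(ny_um, nx_um)
        self._validate_bodies()

    def _validate_bodies(self) -> None:
        nz, ny, nx = self.shape
        vx, vy, vz = self.voxel_size_um
        extent = (nz * vz, ny * vy, nx * vx)
        cy, cx = self.cell_center_um
        for i, b in enumerate(self.bodies):
            support = 3.0 * b.sigma_um
            z, y, x = b.center_um
            if not (
                support <= z <= extent[0] - support
                and support <= y <= extent[1] - support
                and support <= x <= extent[2] - support
            ):
                raise ValueError(
                    f"body {i} at {b.center_um} µm (support {support:.2f} µm) "
                    f"extends outside the image extent {extent}"
                )
            if math.hypot(y - cy, x - cx) > self.cell_radius_um:
                raise ValueError(f"body {i} lies outside the cell mask")

    @property
    def voxel(self) -> VoxelSize:
        return VoxelSize(*self.voxel_size_um)

    def cell_mask(self) -> np.ndarray:
        """2-D boolean in-plane disk mask of the cell."""
        _, ny, nx = self.shape
        vx, vy, _ = self.voxel_size_um
        yy = (np.arange(ny) + 0.5) * vy
        xx = (np.arange(nx) + 0.5) * vx
        cy, cx = self.cell_center_um
        dist2 = (yy[:, None] - cy) ** 2 + (xx[None, :] - cx) ** 2
        return dist2 <= self.cell_radius_um**2

    def _voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        nz, ny, nx = self.shape
        vx, vy, vz = self.voxel_size_um
        return (
            (np.arange(nz) + 0.5) * vz,
            (np.arange(ny) + 0.5) * vy,
            (np.arange(nx) + 0.5) * vx,
        )

    def body_footprint_voxels(self, index: int, threshold: float) -> np.ndarray:
        """(n, 3) voxel indices where body ``index`` exceeds ``threshold``.

        Computed from the analytic isophote radius, independently of any
        rendering, so it can serve as a recovery oracle for detectors.
        """
        body = self.bodies[index]
        r = body.isophote_radius_um(threshold)
        zz, yy, xx = self._voxel_centers()
        bz, by, bx = body.center_um
        d2 = (
            (zz[:, None, None] - bz) ** 2
            + (yy[None, :, None] - by) ** 2
            + (xx[None, None, :] - bx) ** 2
        )
        return np.argwhere(d2 <= r**2)

    # -- JSON manifest -----------------------------------------------------

    def to_json(self) -> str:
        payload = asdict(self)
        payload["kind"] = "image_ground_truth"
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ImageGroundTruth":
        payload = json.loads(text)
        payload.pop("kind", None)
        bodies = [PlantedBody(**{**b, "center_um": tuple(b["center_um"])}) for b in payload.pop("bodies")]
        payload["shape"] = tuple(payload["shape"])
        payload["voxel_size_um"] = tuple(payload["voxel_size_um"])
        if payload.get("cell_center_um") is not None:
            payload["cell_center_um"] = tuple(payload["cell_center_um"])
        return cls(bodies=bodies, **payload)


def generate_image(truth: ImageGroundTruth, seed: int = 0) -> ConfocalStack:
    """Render a synthetic confocal stack from planted ground truth.

    Each body contributes ``peak * exp(-d² / 2σ²)`` (zero beyond 3σ) to the
    reduced channel and ``true_ratio`` times that to the oxidised channel;
    the chlorophyll channel is a constant level inside the cell mask. With
    ``poisson_noise`` the expected intensities are replaced by Poisson draws
    (shot noise); Gaussian read noise of sd ``gaussian_noise_sd`` is then
    added per channel. Noise is independent across channels and voxels.
    """
    rng = np.random.default_rng(seed)
    nz, ny, nx = truth.shape
    reduced = np.zeros(truth.shape)
    oxidised = np.zeros(truth.shape)
    zz, yy, xx = truth._voxel_centers()

    for body in truth.bodies:
        bz, by, bx = body.center_um
        sigma = body.sigma_um
        support = 3.0 * sigma
        # restrict rendering to the truncation bounding box
        zi = np.flatnonzero(np.abs(zz - bz) <= support)
        yi = np.flatnonzero(np.abs(yy - by) <= support)
        xi = np.flatnonzero(np.abs(xx - bx) <= support)
        d2 = (
            (zz[zi][:, None, None] - bz) ** 2
            + (yy[yi][None, :, None] - by) ** 2
            + (xx[xi][None, None, :] - bx) ** 2
        )
        profile = np.where(
            d2 <= support**2,
            body.peak_reduced_intensity * np.exp(-d2 / (2.0 * sigma**2)),
            0.0,
        )
        sub = np.ix_(zi, yi, xi)
        reduced[sub] += profile
        oxidised[sub] += profile * body.true_ratio

    mask2d = truth.cell_mask()
    chlorophyll = np.where(mask2d[None, :, :], truth.chlorophyll_level, 0.0) * np.ones(
        (nz, 1, 1)
    )

    channels = {"oxidised": oxidised, "reduced": reduced, "chlorophyll": chlorophyll}
    for name, img in channels.items():
        noisy = img
        if truth.poisson_noise:
            noisy = rng.poisson(noisy).astype(float)
        if truth.gaussian_noise_sd > 0:
            noisy = noisy + rng.normal(0.0, truth.gaussian_noise_sd, size=img.shape)
            np.clip(noisy, 0.0, None, out=noisy)
        channels[name] = noisy

    return ConfocalStack(
        channels=channels,
        voxel_size=truth.voxel,
        metadata={"synthetic": True, "seed": int(seed), "n_bodies": len(truth.bodies)},
    )


# --------------------------------------------------------------------------
# table ground truth
# --------------------------------------------------------------------------

#: Default latent mixture: endosymbiotic-like, transition, ex-symbiotic-like,
#: on the scale of "multiples of the endosymbiont component mean".
DEFAULT_COMPONENT_MEANS = ((1.0, 1.0), (3.0, 0.52), (6.0, 0.40))
DEFAULT_COMPONENT_COVS = (
    ((0.22**2, 0.0), (0.0, 0.07**2)),
    ((0.35**2, 0.0), (0.0, 0.06**2)),
    ((0.45**2, 0.0), (0.0, 0.05**2)),
)
DEFAULT_WEIGHTS = (0.40, 0.25, 0.35)
#: Probability that a cell of each component is endosymbiotic; the remaining
#: mass is ex-symbiotic. Component 2's 0.34 mirrors the mixed transition
#: profile the pipeline should report as roughly 34:66 endo:ex.
DEFAULT_MIX = (0.90, 0.34, 0.00)
#: Per-species baselines (lipid volume µm³ and LPO ratio of the endosymbiotic
#: component); free choices at realistic magnitudes for dinoflagellate cells.
DEFAULT_SPECIES_SCALES = {
    "M. capitata": (18.0, 1.4),
    "P. compressa": (25.0, 1.7),
    "P. acuta": (20.0, 1.2),
}


@dataclass
class TableGroundTruth:
    """Parameters of the synthetic per-cell study.

    ``n_cells`` and ``n_colonies`` are per species. Colony effects are drawn
    once per colony: N(0, colony_sd_log_volume) added to log lipid volume and
    N(0, colony_sd_lpo) added to the LPO ratio, shared by all that colony's
    cells.
    """

    component_means: tuple = DEFAULT_COMPONENT_MEANS
    component_covariances: tuple = DEFAULT_COMPONENT_COVS
    component_weights: tuple = DEFAULT_WEIGHTS
    celltype_mix_per_component: tuple = DEFAULT_MIX
    n_cells: int = 150
    n_colonies: int = 4
    colony_sd_log_volume: float = 0.05
    colony_sd_lpo: float = 0.03
    species_scales: dict = field(
        default_factory=lambda: dict(DEFAULT_SPECIES_SCALES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.component_means)
        if not (len(self.component_covariances) == len(self.component_weights) == k):
            raise ValueError("component parameter lists disagree on length")
        if len(self.celltype_mix_per_component) != k:
            raise ValueError("need one celltype mix probability per component")
        w = np.asarray(self.component_weights, dtype=float)
        if w.min() < 0 or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("component weights must be non-negative and sum to 1")
        for p in self.celltype_mix_per_component:
            if not 0.0 <= p <= 1.0:
                raise ValueError("celltype mix probabilities must lie in [0, 1]")
        for cov in self.component_covariances:
            c = np.asarray(cov, dtype=float)
            if not np.all(np.linalg.eigvalsh(c) >= -1e-12):
                raise ValueError("component covariances must be positive semi-definite")
        if self.n_cells < 1 or self.n_colonies < 1:
            raise ValueError("n_cells and n_colonies must be >= 1")

    def to_json(self) -> str:
        payload = asdict(self)
        payload["kind"] = "table_ground_truth"
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TableGroundTruth":
        payload = json.loads(text)
        payload.pop("kind", None)
        payload["component_means"] = tuple(tuple(m) for m in payload["component_means"])
        payload["component_covariances"] = tuple(
            tuple(tuple(row) for row in cov) for cov in payload["component_covariances"]
        )
        payload["component_weights"] = tuple(payload["component_weights"])
        payload["celltype_mix_per_component"] = tuple(
            payload["celltype_mix_per_component"]
        )
        payload["species_scales"] = {
            k: tuple(v) for k, v in payload["species_scales"].items()
        }
        return cls(**payload)


def generate_cell_table(
    truth: TableGroundTruth, seed: int | None = None
) -> pd.DataFrame:
    """Draw a synthetic per-cell table with latent component labels.

    Returns a DataFrame with one row per cell: ``cell_id``, ``species``,
    ``colony``, ``cell_type``, ``lipid_volume_um3``, ``lpo_ratio``,
    ``true_component`` (the latent mixture label, 0-based) and ``truncated``
    (True where a non-positive draw was floored). Reproducible for a fixed
    seed (``truth.seed`` unless overridden).
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    k = len(truth.component_weights)
    means = np.asarray(truth.component_means, dtype=float)
    covs = [np.asarray(c, dtype=float) for c in truth.component_covariances]

    rows = []
    cell_id = 0
    for species, (vol_scale, lpo_scale) in truth.species_scales.items():
        colony_names = [f"{species} colony {j + 1}" for j in range(truth.n_colonies)]
        col_vol = rng.normal(0.0, truth.colony_sd_log_volume, size=truth.n_colonies)
        col_lpo = rng.normal(0.0, truth.colony_sd_lpo, size=truth.n_colonies)
        comps = rng.choice(k, size=truth.n_cells, p=truth.component_weights)
        colonies = rng.integers(0, truth.n_colonies, size=truth.n_cells)
        for comp, colony in zip(comps, colonies):
            rel_vol, rel_lpo = rng.multivariate_normal(means[comp], covs[comp])
            truncated = False
            if rel_vol <= 0:
                rel_vol, truncated = VOLUME_FLOOR_UM3, True
            # colony effect multiplicative on volume = additive on its log
            volume = vol_scale * rel_vol * math.exp(col_vol[colony])
            lpo = lpo_scale * rel_lpo + lpo_scale * col_lpo[colony]
            if lpo < 0:
                lpo, truncated = 0.0, True
            is_endo = rng.random() < truth.celltype_mix_per_component[comp]
            rows.append(
                {
                    "cell_id": f"cell-{cell_id:05d}",
                    "species": species,
                    "colony": colony_names[colony],
                    "cell_type": "endosymbiotic" if is_endo else "ex-symbiotic",
                    "lipid_volume_um3": volume,
                    "lpo_ratio": lpo,
                    "true_component": int(comp),
                    "truncated": truncated,
                }
            )
            cell_id += 1
    return pd.DataFrame(rows)
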