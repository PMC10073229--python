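"""Lipid-body detection and per-ROI fluorescence measurement.

Lipid bodies appear as bright blobs in both lipid-dye channels. Detection runs
on the *sum* of the two channels (so a body dim in one channel but bright in
the other is still found), lightly Gaussian-smoothed in-plane, thresholded
(Otsu within the cell mask by default, or a fixed absolute value), and
labelled as 26-connected 3-D components so a body spanning z-slices is a
single ROI. Per-channel means are always measured on the *raw* channels; the
smoothed image is used only to decide which voxels belong to a body, keeping
the oxidised/reduced ratio unbiased.

Areas are reported in µm² by summing in-plane pixel areas across every slice
an ROI touches, matching the downstream volume estimate (summed area × slice
thickness).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import filters, measure

from .stack import ConfocalStack

logger = logging.getLogger(__name__)

#: Sentinel ratio for ROIs whose reduced-channel mean is zero.
RATIO_UNDEFINED = float("nan")


@dataclass
class SegmentationConfig:
    """Detection parameters.

    Attributes
    ----------
    threshold
        ``"otsu"`` (computed within the cell mask) or a fixed absolute value
        applied to the smoothed combined lipid signal.
    smooth_sigma_px
        In-plane Gaussian smoothing sigma in pixels (z is never smoothed:
        slice spacing is typically ~4x the pixel edge).
    min_roi_px
        Minimum voxel count of a component; rejects single-pixel noise.
    """

    threshold: float | str = "otsu"
    smooth_sigma_px: float = 1.0
    min_roi_px: int = 4

    def __post_init__(self) -> None:
        if isinstance(self.threshold, str) and self.threshold != "otsu":
            raise ValueError(f"threshold must be 'otsu' or a number, got {self.threshold!r}")
        if self.smooth_sigma_px < 0:
            raise ValueError("smooth_sigma_px must be >= 0")
        if self.min_roi_px < 1:
            raise ValueError("min_roi_px must be >= 1")


@dataclass
class LipidBodyROI:
    """One detected lipid body.

    ``ratio`` is the ratiometric lipid-peroxidation readout: mean oxidised
    over mean reduced fluorescence across the ROI's voxels. It is NaN
    (undefined) when the reduced mean is zero.
    """

    label: int
    voxels: np.ndarray  # (n, 3) int array of (z, y, x) indices
    area_um2: float
    slice_span: tuple[int, int]
    mean_oxidised: float
    mean_reduced: float
    ratio: float = field(init=False)

    def __post_init__(self) -> None:
        if len(self.voxels) == 0:
            raise ValueError("ROI must contain at least one voxel")
        if self.mean_oxidised < 0 or self.mean_reduced < 0:
            raise ValueError("channel means must be non-negative")
        self.ratio = (
            self.mean_oxidised / self.mean_reduced if self.mean_reduced > 0 else RATIO_UNDEFINED
        )

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)


def measure_roi(
    stack: ConfocalStack, voxels: np.ndarray
) -> tuple[float, float, float]:
    """Measure one voxel set: (mean_oxidised, mean_reduced, area_um2).

    Means are plain arithmetic means of the raw channel intensities over the
    voxels; the area is the voxel count times the in-plane pixel area, i.e.
    in-plane areas summed across all slices the set touches.
    """
    voxels = np.asarray(voxels, dtype=np.intp)
    if voxels.ndim != 2 or voxels.shape[1] != 3 or len(voxels) == 0:
        raise ValueError("voxels must be a non-empty (n, 3) array of (z, y, x) indices")
    shape = stack.shape
    if (voxels < 0).any() or (voxels >= np.array(shape)).any():
        raise IndexError("voxel indices outside stack bounds")
    z, y, x = voxels.T
    mean_ox = float(stack.channel("oxidised")[z, y, x].mean())
    mean_red = float(stack.channel("reduced")[z, y, x].mean())
    area = len(voxels) * stack.voxel_size.pixel_area_um2
    return mean_ox, mean_red, area


def combined_lipid_signal(stack: ConfocalStack, smooth_sigma_px: float = 1.0) -> np.ndarray:
    """Oxidised + reduced signal, Gaussian-smoothed in-plane, used for detection."""
    stack.require_lipid_channels()
    combined = stack.channel("oxidised") + stack.channel("reduced")
    if smooth_sigma_px > 0:
        combined = filters.gaussian(
            combined, sigma=(0.0, smooth_sigma_px, smooth_sigma_px), preserve_range=True
        )
    return combined


def compute_detection_threshold(
    stack: ConfocalStack,
    cell_mask: np.ndarray,
    config: SegmentationConfig | None = None,
) -> float:
    """Threshold actually applied to the smoothed combined signal.

    With ``threshold="otsu"`` the Otsu value is computed over the masked
    voxels only; a constant (e.g. all-zero) masked signal has no Otsu
    threshold, so +inf is returned and no voxel is detected.
    """
    config = config or SegmentationConfig()
    if not isinstance(config.threshold, str):
        return float(config.threshold)
    mask3d = _broadcast_mask(cell_mask, stack.shape)
    values = combined_lipid_signal(stack, config.smooth_sigma_px)[mask3d]
    if values.size == 0 or np.ptp(values) == 0:
        return float("inf")
    return float(filters.threshold_otsu(values))


def _broadcast_mask(cell_mask: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    mask = np.asarray(cell_mask, dtype=bool)
    if mask.ndim == 2:
        mask = np.broadcast_to(mask, shape)
    if mask.shape != shape:
        raise ValueError(f"cell mask shape {mask.shape} incompatible with stack {shape}")
    if not mask.any():
        raise ValueError("cell mask is empty")
    return mask


def segment_lipid_bodies(
    stack: ConfocalStack,
    cell_mask: np.ndarray,
    config: SegmentationConfig | None = None,
) -> list[LipidBodyROI]:
    """Detect lipid-body ROIs inside a cell mask.

    Parameters
    ----------
    stack
        Stack with both lipid channels.
    cell_mask
        2-D (applied to every slice) or 3-D boolean mask of the cell.
    config
        Detection parameters; defaults to Otsu threshold, 1 px smoothing,
        minimum component size 4 voxels.

    Returns
    -------
    list of LipidBodyROI
        Connected components (26-connectivity) of above-threshold voxels,
        largest first. ROIs whose reduced-channel mean is zero are dropped
        with a warning (their oxidised/reduced ratio is undefined).
    """
    config = config or SegmentationConfig()
    stack.require_lipid_channels()
    mask3d = _broadcast_mask(cell_mask, stack.shape)

    threshold = compute_detection_threshold(stack, cell_mask, config)
    binary = (combined_lipid_signal(stack, config.smooth_sigma_px) > threshold) & mask3d
    if not binary.any():
        return []

    labels = measure.label(binary, connectivity=3)  # 26-connectivity in 3-D
    rois: list[LipidBodyROI] = []
    for region in measure.regionprops(labels):
        if region.num_pixels < config.min_roi_px:
            continue
        voxels = np.asarray(region.coords, dtype=np.intp)
        mean_ox, mean_red, area = measure_roi(stack, voxels)
        if mean_red == 0:
            warnings.warn(
                f"ROI {region.label}: reduced-channel mean is zero; "
                "ratio undefined, ROI dropped",
                stacklevel=2,
            )
            continue
        zs = voxels[:, 0]
        rois.append(
            LipidBodyROI(
                label=region.label,
                voxels=voxels,
                area_um2=area,
                slice_span=(int(zs.min()), int(zs.max())),
                mean_oxidised=mean_ox,
                mean_reduced=mean_red,
            )
        )
    rois.sort(key=lambda r: -r.n_voxels)
    logger.info("segmented %d lipid-body ROI(s) at threshold %.4g", len(rois), threshold)
    return rois
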