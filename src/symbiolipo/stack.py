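"""Multichannel confocal z-stack container.

A :class:`ConfocalStack` holds the named fluorescence channels of one imaged
cell (or field of view) together with its voxel geometry. The two lipid-dye
channels are named ``"oxidised"`` (ex/em 488/510, peroxidised lipid) and
``"reduced"`` (ex/em 561/590, intact lipid); an optional ``"chlorophyll"``
channel carries algal autofluorescence. All downstream measurements are
ratiometric in these two lipid channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

#: Channel names every analysis stage requires.
LIPID_CHANNELS = ("oxidised", "reduced")


@dataclass
class VoxelSize:
    """Physical voxel dimensions: in-plane pixel edges and z-slice spacing (µm)."""

    x_um: float
    y_um: float
    z_um: float

    def __post_init__(self) -> None:
        if not (self.x_um > 0 and self.y_um > 0 and self.z_um > 0):
            raise ValueError(f"voxel sizes must be positive, got {self}")

    @property
    def pixel_area_um2(self) -> float:
        return self.x_um * self.y_um

    @property
    def voxel_volume_um3(self) -> float:
        return self.x_um * self.y_um * self.z_um

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.x_um, self.y_um, self.z_um)


@dataclass
class ConfocalStack:
    """A 3-D multichannel fluorescence image with voxel geometry.

    Parameters
    ----------
    channels
        Mapping from channel name to a ``(z, y, x)`` float array. All channels
        must share one shape. The lipid channels ``"oxidised"`` and
        ``"reduced"`` are mandatory for segmentation.
    voxel_size
        Physical voxel dimensions in µm.
    metadata
        Free-form acquisition notes, carried through to provenance records.
    """

    channels: dict[str, np.ndarray]
    voxel_size: VoxelSize
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {name: np.asarray(arr).shape for name, arr in self.channels.items()}
        if not shapes:
            raise ValueError("stack must hold at least one channel")
        distinct = set(shapes.values())
        if len(distinct) != 1:
            raise ValueError(f"channels disagree on shape: {shapes}")
        (shape,) = distinct
        if len(shape) != 3:
            raise ValueError(f"channels must be 3-D (z, y, x), got shape {shape}")
        self.channels = {
            name: np.asarray(arr, dtype=np.float64) for name, arr in self.channels.items()
        }

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        """Return a channel array, raising a clear error if it is absent."""
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"stack has no channel {name!r}; available: {sorted(self.channels)}"
            ) from None

    def require_lipid_channels(self) -> None:
        missing = [c for c in LIPID_CHANNELS if c not in self.channels]
        if missing:
            raise KeyError(
                f"stack is missing required lipid channel(s) {missing}; "
                f"available: {sorted(self.channels)}"
            )

    def scaled(self, factor: float) -> "ConfocalStack":
        """Return a copy with every channel multiplied by ``factor`` (> 0)."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return ConfocalStack(
            channels={k: v * factor for k, v in self.channels.items()},
            voxel_size=self.voxel_size,
            metadata=dict(self.metadata),
        )
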