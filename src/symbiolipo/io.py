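"""Readers and writers for stacks, tables, configs and provenance.

Stacks are stored as multi-page TIFF with axes (channel, z, y, x); voxel
size and channel names travel in the TIFF's shaped-metadata JSON so a
written stack round-trips bit-identically. Tables are CSV (or XLSX for
externally supplied per-cell data) read through pandas with a configurable
column map, since external spreadsheets rarely share our column names.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .stack import ConfocalStack, VoxelSize
from .synthetic import CELL_TYPES

logger = logging.getLogger(__name__)

DEFAULT_CHANNEL_ORDER = ("oxidised", "reduced", "chlorophyll")

#: Our canonical per-cell column names; a column map translates external ones.
CELL_COLUMNS = {
    "cell_id": "cell_id",
    "species": "species",
    "colony": "colony",
    "cell_type": "cell_type",
    "lpo_ratio": "lpo_ratio",
    "lipid_volume_um3": "lipid_volume_um3",
}

#: Spellings commonly found in hand-edited spreadsheets.
CELL_TYPE_ALIASES = {
    "endo": "endosymbiotic",
    "endosymbiont": "endosymbiotic",
    "endosymbiotic": "endosymbiotic",
    "ex": "ex-symbiotic",
    "ex-symbiont": "ex-symbiotic",
    "ex-symbiotic": "ex-symbiotic",
    "exsymbiotic": "ex-symbiotic",
    "expelled": "expelled",
}


# --------------------------------------------------------------------------
# stacks
# --------------------------------------------------------------------------


def write_stack(path, stack: ConfocalStack, channel_order=None) -> None:
    """Write a stack as a (C, Z, Y, X) TIFF with voxel size in metadata."""
    order = [c for c in (channel_order or DEFAULT_CHANNEL_ORDER) if c in stack.channels]
    order += [c for c in stack.channels if c not in order]
    data = np.stack([stack.channels[c] for c in order]).astype(np.float32)
    tifffile.imwrite(
        path,
        data,
        metadata={
            "axes": "CZYX",
            "channel_names": list(order),
            "voxel_size_um": list(stack.voxel_size.as_tuple()),
            "notes": stack.metadata,
        },
    )


def read_stack(
    path,
    pixel_size_um: float | None = None,
    z_step_um: float | None = None,
    channel_names: list[str] | None = None,
) -> ConfocalStack:
    """Read a (C, Z, Y, X) TIFF stack.

    Voxel size and channel names come from the embedded metadata when
    present; otherwise they must be supplied (``pixel_size_um``,
    ``z_step_um``, ``channel_names``) — a missing voxel size raises an error
    telling the caller which override to pass.
    """
    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    except (tifffile.TiffFileError, ValueError) as exc:
        raise ValueError(f"cannot parse TIFF {path}: {exc}") from exc
    if data.ndim == 3:
        data = data[:, None, :, :]  # single-slice stack
    if data.ndim != 4:
        raise ValueError(f"expected a (C, Z, Y, X) stack, got shape {data.shape}")

    names = channel_names or meta.get("channel_names")
    if names is None:
        names = [f"channel{i}" for i in range(data.shape[0])]
        names[: min(2, len(names))] = ["oxidised", "reduced"][: data.shape[0]]
    if len(names) != data.shape[0]:
        raise ValueError(f"{len(names)} channel names for {data.shape[0]} channels")

    voxel = meta.get("voxel_size_um")
    if pixel_size_um is not None or z_step_um is not None:
        if pixel_size_um is None or z_step_um is None:
            raise ValueError("pass both pixel_size_um and z_step_um, or neither")
        voxel = [pixel_size_um, pixel_size_um, z_step_um]
    if voxel is None:
        raise ValueError(
            f"{path} carries no voxel-size metadata; pass pixel_size_um= and "
            "z_step_um= (CLI: --pixel-size-um / --z-step-um)"
        )
    return ConfocalStack(
        channels={n: data[i].astype(np.float64) for i, n in enumerate(names)},
        voxel_size=VoxelSize(*voxel),
        metadata=dict(meta.get("notes", {})),
    )


# --------------------------------------------------------------------------
# tables
# --------------------------------------------------------------------------


def rois_to_frame(rois, cell_id: str = "cell-0") -> pd.DataFrame:
    """Flatten LipidBodyROI objects to the tabular ROI layout."""
    return pd.DataFrame(
        [
            {
                "cell_id": cell_id,
                "label": r.label,
                "n_voxels": r.n_voxels,
                "area_um2": r.area_um2,
                "mean_oxidised": r.mean_oxidised,
                "mean_reduced": r.mean_reduced,
                "ratio": r.ratio,
            }
            for r in rois
        ]
    )


def read_cell_table(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a per-cell table from CSV or XLSX with a configurable column map.

    ``column_map`` maps our canonical names (see :data:`CELL_COLUMNS`) to the
    file's column headers; identity by default. Cell-type strings are coerced
    to the controlled vocabulary; unknown values raise with the offending
    rows listed.
    """
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        raw = pd.read_excel(path)
    else:
        raw = pd.read_csv(path)
    column_map = {**{k: k for k in CELL_COLUMNS}, **(column_map or {})}
    missing = [src for src in column_map.values() if src not in raw.columns]
    if missing:
        raise ValueError(
            f"{path.name} is missing mapped column(s) {missing}; "
            f"column map in effect: {column_map}"
        )
    table = raw[[column_map[k] for k in CELL_COLUMNS]].copy()
    table.columns = list(CELL_COLUMNS)
    coerced = (
        table["cell_type"].astype(str).str.strip().str.lower().map(CELL_TYPE_ALIASES)
    )
    bad = table.index[coerced.isna()]
    if len(bad):
        raise ValueError(
            f"unknown cell_type value(s) {sorted(set(table.loc[bad, 'cell_type']))} "
            f"in rows {bad[:10].tolist()}; expected one of {CELL_TYPES}"
        )
    table["cell_type"] = coerced
    for col in ("lpo_ratio", "lipid_volume_um3"):
        table[col] = pd.to_numeric(table[col], errors="raise").astype(float)
    return table


# --------------------------------------------------------------------------
# config and provenance
# --------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """All pipeline thresholds in one round-trippable structure."""

    # segmentation
    threshold: float | str = "otsu"
    smooth_sigma_px: float = 1.0
    min_roi_px: int = 4
    # inclusion-body exclusion
    min_area_um2: float = 0.2
    max_area_um2: float = 20.0
    max_ratio: float = 5.0
    # geometry
    slice_thickness_um: float = 1.0
    # normalisation
    species_col: str = "species"
    celltype_col: str = "cell_type"
    # clustering
    k: int = 3
    n_init: int = 50
    seed: int = 0
    k_max: int = 6
    gap_bootstraps: int = 100
    # statistics
    model_mode: str = "per_cell"
    transform_policy: str = "auto"  # auto | none | log | sqrt
    # external tables
    column_map: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("smooth_sigma_px",):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("min_area_um2", "max_area_um2", "max_ratio", "slice_thickness_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls(**(yaml.safe_load(text) or {}))

    def save(self, path) -> None:
        Path(path).write_text(self.to_yaml())

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_yaml(Path(path).read_text())


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_provenance(path, config: PipelineConfig, inputs=(), seeds=None, extra=None) -> None:
    """Emit the provenance JSON that accompanies every output table."""
    from . import __version__

    record = {
        "software": {"name": "symbiolipo", "version": __version__},
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": asdict(config),
        "seeds": seeds or {},
        "inputs": {str(p): file_sha256(p) for p in inputs if Path(p).exists()},
    }
    if extra:
        record.update(extra)
    Path(path).write_text(json.dumps(record, indent=2, default=str))
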