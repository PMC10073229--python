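"""Per-cell metrics from lipid-body ROI tables.

Converts detected ROIs into the two quantities analysed per cell:

* **LPO ratio** — the unweighted arithmetic mean of the oxidised/reduced
  ratios of the cell's lipid bodies (each body counts once regardless of
  size; an area-weighted variant is available but off by default).
* **Lipid volume** — the summed in-plane ROI area multiplied by the z-slice
  focal thickness (µm³).

Before either is computed, inclusion bodies — large, round, highly
fluorescent structures that are not lipid stores — are removed with explicit
area and ratio cut-offs. Host gastroderm cells imaged with two symbionts are
collapsed to a single measurement by averaging the pair.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .segmentation import LipidBodyROI

logger = logging.getLogger(__name__)

DEFAULT_SLICE_THICKNESS_UM = 1.0


@dataclass
class ExclusionConfig:
    """Inclusion-body cut-offs: keep ROIs with area in [min, max] µm² and
    ratio <= max_ratio. Values are deliberately explicit — they stand in for
    a manual curation step and are recorded in output provenance."""

    min_area_um2: float = 0.2
    max_area_um2: float = 20.0
    max_ratio: float = 5.0

    def __post_init__(self) -> None:
        if not self.min_area_um2 < self.max_area_um2:
            raise ValueError("min_area_um2 must be below max_area_um2")
        if self.max_ratio <= 0:
            raise ValueError("max_ratio must be positive")

    def keeps(self, area_um2: float, ratio: float) -> bool:
        return (
            self.min_area_um2 <= area_um2 <= self.max_area_um2
            and not math.isnan(ratio)
            and ratio <= self.max_ratio
        )


def exclude_inclusion_bodies(
    rois: list[LipidBodyROI], config: ExclusionConfig | None = None
) -> tuple[list[LipidBodyROI], list[LipidBodyROI]]:
    """Partition ROIs into (kept, excluded) by the configured cut-offs.

    An ROI is excluded iff its area falls outside the configured range or its
    ratio exceeds ``max_ratio``. Both partitions are returned so exclusions
    stay auditable. Idempotent: re-filtering the kept list changes nothing.
    """
    config = config or ExclusionConfig()
    kept = [r for r in rois if config.keeps(r.area_um2, r.ratio)]
    excluded = [r for r in rois if not config.keeps(r.area_um2, r.ratio)]
    if excluded:
        logger.info("excluded %d of %d ROI(s) as inclusion bodies", len(excluded), len(rois))
    return kept, excluded


def cell_lpo_ratio(kept_rois: list[LipidBodyROI], area_weighted: bool = False) -> float:
    """Per-cell LPO ratio: mean of the ROI ratios.

    Unweighted by default — every lipid body contributes equally. Raises on
    an empty list; callers flag such cells "no-lipid" and drop them from
    ratio analyses (see :func:`cells_from_rois`).
    """
    if not kept_rois:
        raise ValueError("cell has no kept lipid bodies; LPO ratio undefined")
    if area_weighted:
        total_area = sum(r.area_um2 for r in kept_rois)
        return sum(r.ratio * r.area_um2 for r in kept_rois) / total_area
    return sum(r.ratio for r in kept_rois) / len(kept_rois)


def cell_lipid_volume(
    kept_rois: list[LipidBodyROI], slice_thickness_um: float = DEFAULT_SLICE_THICKNESS_UM
) -> float:
    """Total lipid-store volume: (Σ ROI area µm²) × slice thickness µm."""
    if slice_thickness_um <= 0:
        raise ValueError("slice_thickness_um must be positive")
    return sum(r.area_um2 for r in kept_rois) * slice_thickness_um


def cells_from_rois(
    roi_table: pd.DataFrame,
    exclusion: ExclusionConfig | None = None,
    slice_thickness_um: float = DEFAULT_SLICE_THICKNESS_UM,
    area_weighted: bool = False,
) -> pd.DataFrame:
    """Aggregate a per-ROI table (one row per ROI, with a ``cell_id`` column
    and optional ``species``/``colony``/``cell_type``/``host_cell_id``) into
    one row per cell: lpo_ratio, lipid_volume_um3, n_lipid_bodies.

    Cells whose every ROI is excluded are flagged ``no_lipid`` (volume 0,
    ratio NaN) and counted in the log rather than silently dropped.
    """
    exclusion = exclusion or ExclusionConfig()
    required = {"cell_id", "area_um2", "ratio"}
    missing = required - set(roi_table.columns)
    if missing:
        raise ValueError(f"ROI table missing column(s): {sorted(missing)}")

    carry = [
        c for c in ("host_cell_id", "species", "colony", "cell_type") if c in roi_table.columns
    ]
    out = []
    n_no_lipid = 0
    for cell_id, group in roi_table.groupby("cell_id", sort=True):
        keep = group[
            group["area_um2"].between(exclusion.min_area_um2, exclusion.max_area_um2)
            & (group["ratio"] <= exclusion.max_ratio)
        ]
        row = {"cell_id": cell_id}
        for c in carry:
            row[c] = group[c].iloc[0]
        if len(keep) == 0:
            n_no_lipid += 1
            row.update(lpo_ratio=float("nan"), lipid_volume_um3=0.0, n_lipid_bodies=0, no_lipid=True)
        else:
            if area_weighted:
                ratio = (keep["ratio"] * keep["area_um2"]).sum() / keep["area_um2"].sum()
            else:
                ratio = keep["ratio"].mean()
            row.update(
                lpo_ratio=float(ratio),
                lipid_volume_um3=float(keep["area_um2"].sum() * slice_thickness_um),
                n_lipid_bodies=int(len(keep)),
                no_lipid=False,
            )
        out.append(row)
    if n_no_lipid:
        logger.info("%d cell(s) flagged no-lipid (all ROIs excluded)", n_no_lipid)
    return pd.DataFrame(out)


def aggregate_cohosted(cells: pd.DataFrame) -> pd.DataFrame:
    """Collapse co-hosted endosymbiont pairs to one measurement per host cell.

    Rows sharing a non-null ``host_cell_id`` must be 1–2 endosymbiotic
    records; a pair is replaced by the arithmetic mean of its ``lpo_ratio``
    and ``lipid_volume_um3`` (and the sum of ``n_lipid_bodies`` if present).
    Rows without a host_cell_id pass through unchanged.
    """
    if "host_cell_id" not in cells.columns:
        return cells.copy()
    loose = cells[cells["host_cell_id"].isna()]
    hosted = cells[cells["host_cell_id"].notna()]
    rows = [loose]
    for host_id, group in hosted.groupby("host_cell_id", sort=True):
        if len(group) > 2:
            raise ValueError(
                f"host cell {host_id!r} has {len(group)} symbiont records; "
                "the study design allows at most two per gastroderm cell"
            )
        if "cell_type" in group.columns and not (group["cell_type"] == "endosymbiotic").all():
            raise ValueError(
                f"host cell {host_id!r} groups non-endosymbiotic records; "
                "only endosymbionts share a host cell"
            )
        merged = group.iloc[[0]].copy()
        if len(group) == 2:
            merged["lpo_ratio"] = group["lpo_ratio"].mean()
            merged["lipid_volume_um3"] = group["lipid_volume_um3"].mean()
            if "n_lipid_bodies" in group.columns:
                merged["n_lipid_bodies"] = group["n_lipid_bodies"].sum()
            merged["cell_id"] = str(host_id)
        rows.append(merged)
    return pd.concat(rows, ignore_index=True)
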