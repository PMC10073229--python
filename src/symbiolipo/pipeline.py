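"""End-to-end pipeline: stacks → ROIs → cells → normalise → cluster → stats.

Each stage writes its table plus a provenance JSON into the output
directory and is skipped on rerun if its output already exists, so a run
can resume from any completed stage (delete a stage's output to recompute
it and everything downstream of it was NOT automatically invalidated — the
stage files are independent, matching a make-like contract).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, metrics, stats
from .io import PipelineConfig, read_cell_table, read_stack, rois_to_frame, write_provenance
from .segmentation import SegmentationConfig, segment_lipid_bodies

logger = logging.getLogger(__name__)

STAGE_FILES = {
    "rois": "rois.csv",
    "cells": "cells.csv",
    "normalised": "normalised.csv",
    "cluster": "assignments.csv",
    "stats": "model_terms.csv",
}


def _stage_done(out_dir: Path, stage: str) -> bool:
    return (out_dir / STAGE_FILES[stage]).exists()


def _write(out_dir: Path, stage: str, frame: pd.DataFrame, config: PipelineConfig, **extra):
    path = out_dir / STAGE_FILES[stage]
    frame.to_csv(path, index=False)
    write_provenance(
        path.with_suffix(".provenance.json"),
        config,
        seeds={"seed": config.seed},
        extra={"stage": stage, **extra},
    )
    logger.info("stage %-10s → %s (%d rows)", stage, path.name, len(frame))


def run_pipeline(
    config: PipelineConfig,
    out_dir,
    cell_table=None,
    stacks_dir=None,
    cell_metadata: pd.DataFrame | None = None,
) -> Path:
    """Run all applicable stages and return the output directory.

    Provide either ``stacks_dir`` (a directory of per-cell TIFF stacks; the
    whole field of view is used as the cell mask unless a matching
    ``<stem>.mask.tif`` exists) together with optional ``cell_metadata``
    (cell_id → species/colony/cell_type), or ``cell_table`` (CSV/XLSX of
    already-quantified cells, read through ``config.column_map``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if cell_table is None and stacks_dir is None:
        raise ValueError("provide cell_table or stacks_dir")

    # --- segmentation + per-cell metrics (image route) ---------------------
    if stacks_dir is not None:
        if not _stage_done(out_dir, "rois"):
            seg_cfg = SegmentationConfig(
                threshold=config.threshold,
                smooth_sigma_px=config.smooth_sigma_px,
                min_roi_px=config.min_roi_px,
            )
            frames = []
            paths = sorted(Path(stacks_dir).glob("*.tif*"))
            if not paths:
                raise FileNotFoundError(f"no TIFF stacks in {stacks_dir}")
            for path in paths:
                if ".mask" in path.suffixes or ".mask" in path.stem:
                    continue
                stack = read_stack(path)
                mask_path = path.with_name(path.stem + ".mask.tif")
                if mask_path.exists():
                    mask = read_stack(mask_path).channels.popitem()[1] > 0
                else:
                    mask = np.ones(stack.shape[1:], dtype=bool)
                rois = segment_lipid_bodies(stack, mask, seg_cfg)
                frames.append(rois_to_frame(rois, cell_id=path.stem))
            _write(out_dir, "rois", pd.concat(frames, ignore_index=True), config)
        if not _stage_done(out_dir, "cells"):
            roi_table = pd.read_csv(out_dir / STAGE_FILES["rois"])
            if cell_metadata is not None:
                roi_table = roi_table.merge(cell_metadata, on="cell_id", how="left")
            cells = metrics.cells_from_rois(
                roi_table,
                metrics.ExclusionConfig(
                    config.min_area_um2, config.max_area_um2, config.max_ratio
                ),
                slice_thickness_um=config.slice_thickness_um,
            )
            if "host_cell_id" in cells.columns:
                cells = metrics.aggregate_cohosted(cells)
            _write(out_dir, "cells", cells, config)
    elif not _stage_done(out_dir, "cells"):
        table = (
            read_cell_table(cell_table, config.column_map)
            if isinstance(cell_table, (str, Path))
            else cell_table.copy()
        )
        _write(out_dir, "cells", table, config)

    # --- normalisation ------------------------------------------------------
    if not _stage_done(out_dir, "normalised"):
        cells = pd.read_csv(out_dir / STAGE_FILES["cells"])
        cells = cells[~cells.get("no_lipid", pd.Series(False, index=cells.index)).fillna(False)]
        normed = stats.normalise_to_endosymbiont_mean(
            cells, species_col=config.species_col, celltype_col=config.celltype_col
        )
        _write(out_dir, "normalised", normed, config)

    # --- clustering ---------------------------------------------------------
    if not _stage_done(out_dir, "cluster"):
        normed = pd.read_csv(out_dir / STAGE_FILES["normalised"])
        points = normed[list(clustering.FEATURES)].to_numpy()
        report = clustering.select_k(
            points,
            k_range=range(1, config.k_max + 1),
            B=config.gap_bootstraps,
            seed=config.seed,
        )
        model = clustering.kmeans_fit(
            points, k=config.k, n_init=config.n_init, seed=config.seed
        )
        normed["cluster"] = model.assignments
        comp = clustering.composition(model, normed[config.celltype_col])
        _write(out_dir, "cluster", normed, config, wss=model.wss)
        report.to_frame().to_csv(out_dir / "k_selection.csv", index=False)
        comp.counts.join(comp.percentages, rsuffix="_pct").to_csv(
            out_dir / "composition.csv"
        )

    # --- statistics ---------------------------------------------------------
    if not _stage_done(out_dir, "stats"):
        normed = pd.read_csv(out_dir / STAGE_FILES["normalised"])
        rows = []
        for var in ("rel_lpo_ratio", "rel_lipid_volume_um3"):
            for species, sub in normed.groupby(config.species_col):
                sub = sub[sub[config.celltype_col].isin(["endosymbiotic", "ex-symbiotic"])]
                if sub[config.celltype_col].nunique() < 2 or sub[config.species_col].count() < 4:
                    continue
                values, kind = apply_transform_policy(
                    sub[var], sub[config.celltype_col], config.transform_policy
                )
                sub = sub.assign(_response=values)
                try:
                    fit = stats.fit_mixed_model(
                        sub,
                        "_response",
                        fixed_effects=[config.celltype_col],
                        group_col="colony",
                        mode=config.model_mode,
                    )
                except ValueError as exc:
                    logger.warning("skipping %s / %s: %s", var, species, exc)
                    continue
                frame = fit.to_frame()
                frame.insert(0, "species", species)
                frame.insert(1, "variable", var)
                frame.insert(2, "transform", kind)
                frame["boundary"] = fit.boundary
                rows.append(frame)
        terms = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
        _write(out_dir, "stats", terms, config)

    return out_dir


def apply_transform_policy(values, groups, policy: str = "auto"):
    """Pick and apply the transform the assumption checks call for.

    ``auto`` tries none → log (positive data only) → sqrt, keeping the first
    under which Shapiro-Wilk and Levene both pass at 0.05, else the last
    viable one. Explicit policies apply directly. Returns (array, kind).
    """
    vals = np.asarray(values, dtype=float)
    if policy != "auto":
        return stats.transform(vals, policy), policy
    candidates = ["none"] + (["log"] if (vals > 0).all() else []) + ["sqrt"]
    chosen = candidates[-1]
    for kind in candidates:
        try:
            report = stats.check_assumptions(stats.transform(vals, kind), np.asarray(groups))
        except ValueError:
            continue
        if report.normal and report.homoscedastic:
            chosen = kind
            break
    return stats.transform(vals, chosen), chosen
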