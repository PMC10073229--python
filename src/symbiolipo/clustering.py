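"""K-means metabolic phenotyping of symbiont cells.

Cells are clustered by Euclidean K-means in the 2-D feature space
(relative lipid volume, relative LPO ratio). Both axes are dimensionless
ratios near 1, so no further standardisation is applied by default (a
z-scoring option exists). The cluster count is chosen by three standard
diagnostics — the within-cluster sum-of-squares elbow, mean silhouette
width, and the gap statistic with bootstrap reference samples drawn
uniformly over the data's bounding box (Tibshirani's simplest reference).

Clusters are numbered by *descending* centroid LPO ratio, so cluster 1 is
always the high-LPO / low-lipid, endosymbiotic-like profile and the last
cluster the low-LPO / high-lipid, ex-symbiotic-like profile, regardless of
initialisation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

logger = logging.getLogger(__name__)

DEFAULT_N_INIT = 50
#: Feature order: (relative lipid volume, relative LPO ratio).
FEATURES = ("rel_lipid_volume_um3", "rel_lpo_ratio")
LPO_AXIS = 1  # index of the LPO feature, used for cluster ordering
KNOWN_CELL_TYPES = ("endosymbiotic", "ex-symbiotic", "expelled")


@dataclass
class ClusterModel:
    """A fitted K-means solution, clusters ordered by descending LPO."""

    k: int
    centroids: np.ndarray  # (k, n_features)
    assignments: np.ndarray  # label in 1..k per training point
    wss: float
    seed: int
    n_init: int
    zscored: bool = False
    feature_means: np.ndarray | None = None
    feature_sds: np.ndarray | None = None

    def __post_init__(self) -> None:
        lpo = self.centroids[:, LPO_AXIS]
        if not np.all(np.diff(lpo) <= 1e-12):
            raise ValueError("centroids must be ordered by descending LPO ratio")


def _prepare(points, zscore: bool, means=None, sds=None):
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2:
        raise ValueError("points must be a 2-D array (n_cells, n_features)")
    if not np.isfinite(pts).all():
        raise ValueError("points contain non-finite values")
    if zscore:
        if means is None:
            means, sds = pts.mean(axis=0), pts.std(axis=0)
            sds = np.where(sds == 0, 1.0, sds)
        pts = (pts - means) / sds
    return pts, means, sds


def kmeans_fit(
    points,
    k: int = 3,
    n_init: int = DEFAULT_N_INIT,
    seed: int = 0,
    zscore: bool = False,
) -> ClusterModel:
    """Euclidean K-means, best of ``n_init`` k-means++ restarts by WSS.

    Deterministic for a fixed seed. If the data hold fewer than ``k``
    distinct points the degenerate duplicates are reported with a warning
    rather than an exception. Cluster labels are 1-based and ordered by
    descending centroid LPO ratio.
    """
    pts, means, sds = _prepare(points, zscore)
    n = len(pts)
    if n < k:
        raise ValueError(f"need at least k={k} points, got {n}")
    n_distinct = len(np.unique(pts, axis=0))
    if n_distinct < k:
        warnings.warn(
            f"only {n_distinct} distinct points for k={k}; clusters degenerate",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn duplicates warning handled above
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, tol=1e-6).fit(pts)
    order = np.argsort(-km.cluster_centers_[:, LPO_AXIS], kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    centroids = km.cluster_centers_[order]
    if zscore:
        centroids = centroids * sds + means  # report centroids on the data scale
    return ClusterModel(
        k=k,
        centroids=centroids,
        assignments=relabel[km.labels_],
        wss=float(km.inertia_),
        seed=seed,
        n_init=n_init,
        zscored=zscore,
        feature_means=means,
        feature_sds=sds,
    )


def assign_to_model(model: ClusterModel, new_points) -> np.ndarray:
    """Nearest-centroid assignment of new cells without refitting.

    Ties go to the lowest cluster index. Training points map back to their
    training assignments.
    """
    pts = np.asarray(new_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != model.centroids.shape[1]:
        raise ValueError(
            f"points must have {model.centroids.shape[1]} features, got shape {pts.shape}"
        )
    if model.zscored:
        pts = (pts - model.feature_means) / model.feature_sds
        centroids = (model.centroids - model.feature_means) / model.feature_sds
    else:
        centroids = model.centroids
    d2 = ((pts[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1) + 1  # argmin breaks ties toward the lowest index


# --------------------------------------------------------------------------
# choosing k
# --------------------------------------------------------------------------


@dataclass
class KSelectionReport:
    k_range: list[int]
    wss_curve: list[float]
    silhouette: dict[int, float]  # mean silhouette width per k (k >= 2)
    gap: dict[int, float]
    gap_se: dict[int, float]
    recommended: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k_range,
                "wss": self.wss_curve,
                "silhouette": [self.silhouette.get(k, np.nan) for k in self.k_range],
                "gap": [self.gap.get(k, np.nan) for k in self.k_range],
                "gap_se": [self.gap_se.get(k, np.nan) for k in self.k_range],
            }
        )


def select_k(
    points,
    k_range=range(1, 7),
    B: int = 100,
    seed: int = 0,
    n_init: int = 10,
) -> KSelectionReport:
    """Evaluate candidate cluster counts by WSS, silhouette and gap statistic.

    gap(k) = mean_b log WSS*_b(k) - log WSS(k) over ``B`` reference datasets
    drawn uniformly within the data's bounding box; its standard error
    carries the usual sqrt(1 + 1/B) bootstrap inflation. Recommendations:
    ``"silhouette"`` = argmax mean silhouette width (k >= 2); ``"gap"`` =
    smallest k with gap(k) >= gap(k+1) - se(k+1) (the one-standard-error
    rule); ``"wss"`` reports the largest relative elbow in the WSS curve.
    """
    if B < 2:
        raise ValueError("gap statistic needs B >= 2 bootstrap samples")
    pts, _, _ = _prepare(points, zscore=False)
    n = len(pts)
    k_range = [int(k) for k in k_range]
    if min(k_range) < 1 or max(k_range) > n - 1:
        raise ValueError(f"k_range must lie within [1, n-1] = [1, {n - 1}]")
    rng = np.random.default_rng(seed)
    lo, hi = pts.min(axis=0), pts.max(axis=0)

    def wss_of(data, k, state) -> float:
        if k == 1:
            centre = data.mean(axis=0)
            return float(((data - centre) ** 2).sum())
        km = KMeans(n_clusters=k, n_init=n_init, random_state=state, tol=1e-6).fit(data)
        return float(km.inertia_)

    wss_curve, sil, gap, gap_se = [], {}, {}, {}
    refs = [rng.uniform(lo, hi, size=pts.shape) for _ in range(B)]
    for k in k_range:
        state = int(rng.integers(0, 2**31 - 1))
        if k == 1:
            wss = wss_of(pts, 1, state)
        else:
            km = KMeans(n_clusters=k, n_init=n_init, random_state=state, tol=1e-6).fit(pts)
            wss = float(km.inertia_)
            if len(set(km.labels_)) > 1:
                sil[k] = float(silhouette_score(pts, km.labels_))
        wss_curve.append(wss)
        log_ref = np.array(
            [
                np.log(wss_of(ref, k, int(rng.integers(0, 2**31 - 1))))
                for ref in refs
            ]
        )
        gap[k] = float(log_ref.mean() - np.log(wss))
        gap_se[k] = float(log_ref.std(ddof=0) * np.sqrt(1.0 + 1.0 / B))

    recommended: dict[str, int] = {}
    if sil:
        recommended["silhouette"] = max(sil, key=sil.get)
    ks = sorted(gap)
    rec_gap = ks[-1]
    for a, b in zip(ks[:-1], ks[1:]):
        if gap[a] >= gap[b] - gap_se[b]:
            rec_gap = a
            break
    recommended["gap"] = rec_gap
    if len(wss_curve) >= 3:
        drops = -np.diff(wss_curve)
        elbow = int(np.argmax(drops[:-1] / np.maximum(drops[1:], 1e-12)))
        recommended["wss"] = k_range[elbow + 1]
    return KSelectionReport(
        k_range=k_range,
        wss_curve=wss_curve,
        silhouette=sil,
        gap=gap,
        gap_se=gap_se,
        recommended=recommended,
    )


# --------------------------------------------------------------------------
# composition and condition shifts
# --------------------------------------------------------------------------


@dataclass
class CompositionSummary:
    """Per-cluster endosymbiotic vs ex-symbiotic composition."""

    counts: pd.DataFrame  # index: cluster 1..k; columns: cell types
    percentages: pd.DataFrame  # same shape; NaN rows for empty clusters

    def endo_ex(self, cluster: int) -> tuple[float, float]:
        row = self.percentages.loc[cluster]
        return float(row.get("endosymbiotic", np.nan)), float(row.get("ex-symbiotic", np.nan))


def composition(model_or_labels, cell_types) -> CompositionSummary:
    """Count and percentage of each cell type within each cluster.

    ``model_or_labels`` is a fitted :class:`ClusterModel` (its training
    assignments are used) or an explicit 1-based label array. Unknown cell
    types raise. Empty clusters are reported with zero counts and NaN
    percentages.
    """
    labels = (
        model_or_labels.assignments
        if isinstance(model_or_labels, ClusterModel)
        else np.asarray(model_or_labels, dtype=int)
    )
    k = (
        model_or_labels.k
        if isinstance(model_or_labels, ClusterModel)
        else int(labels.max())
    )
    types = pd.Series(np.asarray(cell_types, dtype=object))
    if len(types) != len(labels):
        raise ValueError("cell_types and assignments must align")
    unknown = sorted(set(types) - set(KNOWN_CELL_TYPES))
    if unknown:
        raise ValueError(f"unknown cell type label(s): {unknown}")
    counts = (
        pd.crosstab(pd.Series(labels, name="cluster"), types)
        .reindex(index=range(1, k + 1), fill_value=0)
        .reindex(columns=[t for t in KNOWN_CELL_TYPES if t in set(types)], fill_value=0)
    )
    totals = counts.sum(axis=1)
    percentages = counts.div(totals.replace(0, np.nan), axis=0) * 100.0
    return CompositionSummary(counts=counts, percentages=percentages)


def cluster_shift(
    control_labels,
    control_types,
    treated_labels,
    treated_types,
    control_colonies=None,
    treated_colonies=None,
) -> pd.DataFrame:
    """How endosymbionts redistribute across clusters between conditions.

    For each condition the endosymbiotic cells are tallied by cluster and
    expressed as a proportion of that condition's endosymbionts (so each
    condition's proportions sum to 1); the difference (treated - control)
    per cluster quantifies the shift. With colony vectors supplied, the same
    summary is returned per colony as well as pooled (colony = "(pooled)").
    A condition with zero endosymbionts yields NaN proportions.
    """

    def tally(labels, types, colonies, condition):
        labels = np.asarray(labels, dtype=int)
        types = np.asarray(types, dtype=object)
        colonies = (
            np.asarray(colonies, dtype=object)
            if colonies is not None
            else np.full(len(labels), "(pooled)", dtype=object)
        )
        frames = []
        groups = [("(pooled)", np.ones(len(labels), bool))]
        if colonies is not None and len(set(colonies)) > 1:
            groups += [(c, colonies == c) for c in sorted(set(colonies))]
        for colony, sel in groups:
            endo = sel & (types == "endosymbiotic")
            total = int(endo.sum())
            for cl in sorted(set(np.concatenate([labels, np.asarray([], int)]))):
                cnt = int((endo & (labels == cl)).sum())
                frames.append(
                    {
                        "condition": condition,
                        "colony": colony,
                        "cluster": cl,
                        "n_endosymbiotic": cnt,
                        "proportion": cnt / total if total else np.nan,
                    }
                )
        return pd.DataFrame(frames)

    ctrl = tally(control_labels, control_types, control_colonies, "control")
    trt = tally(treated_labels, treated_types, treated_colonies, "treated")
    merged = pd.merge(
        ctrl,
        trt,
        on=["colony", "cluster"],
        how="outer",
        suffixes=("_control", "_treated"),
    ).fillna({"n_endosymbiotic_control": 0, "n_endosymbiotic_treated": 0})
    merged["difference"] = merged["proportion_treated"] - merged["proportion_control"]
    return merged[
        [
            "colony",
            "cluster",
            "n_endosymbiotic_control",
            "proportion_control",
            "n_endosymbiotic_treated",
            "proportion_treated",
            "difference",
        ]
    ].sort_values(["colony", "cluster"], ignore_index=True)
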