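"""Tissue-space cluster validation.

A voxel-wise cluster is an intensity-based finding; validation re-measures it
in each subject's full-resolution native image through segmentation-derived
densities and tests the group difference directly:

* label density = 100 x (segmented voxels inside the cluster) / (cluster
  voxels) — a percentage of cluster volume occupied by signal;
* cell density = (6-connected cells whose centroid lies inside the cluster)
  / (cluster physical volume in mm^3), optionally restricted to an anatomical
  mask (e.g. regions with catecholaminergic somata).

A cluster is *valid* when an unpaired, pooled-variance, one-tailed t-test in
the direction of the voxel-wise effect gives p < alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .core import BinaryMask, GridSpec, check_same_grid
from .preprocess import connectivity_structure
from .spaces import AffineTransform, warp_clusters_to_tissue
from .voxstats import ClusterMap

logger = logging.getLogger(__name__)

DIRECTIONS = ("A>B", "B>A")
METRICS = ("label_density", "cell_density")


@dataclass
class SubjectData:
    """Per-subject inputs to validation, all in tissue space."""

    subject_id: str
    group: str
    segmentation: Optional[BinaryMask]
    grid: GridSpec
    transform: Optional[AffineTransform] = None  # tissue -> atlas; None = identity


@dataclass
class ValidationRecord:
    cluster_id: int
    metric: str
    per_subject: Dict[str, float]
    direction: str
    t_statistic: float
    p_one_tailed: float
    valid: bool
    cluster_volume_mm3: float


def label_density(seg: BinaryMask, cluster: BinaryMask) -> float:
    """Percent of cluster voxels occupied by segmented signal."""
    check_same_grid(seg, cluster, "label_density")
    n_cluster = cluster.n_voxels
    if n_cluster == 0:
        raise ValueError("cluster is empty")
    n_in = int(np.count_nonzero(seg.astype_bool() & cluster.astype_bool()))
    return 100.0 * n_in / n_cluster


def cell_density(
    cell_seg: BinaryMask,
    cluster: BinaryMask,
    restriction: Optional[BinaryMask] = None,
) -> float:
    """Cells per mm^3 of cluster volume.

    Cells are 6-connected components of the segmentation; a cell belongs to
    the cluster when its centroid voxel (nearest voxel to the centroid) lies
    inside the cluster (intersected with the restriction mask if given), so a
    boundary-touching cell is counted exactly once, deterministically.
    """
    check_same_grid(cell_seg, cluster, "cell_density")
    effective = cluster.astype_bool()
    if restriction is not None:
        check_same_grid(cluster, restriction, "cell_density restriction")
        effective = effective & restriction.astype_bool()
    n_eff = int(effective.sum())
    if n_eff == 0:
        raise ValueError("effective cluster (cluster ∩ restriction) is empty")
    labels, n = ndimage.label(cell_seg.astype_bool(), structure=connectivity_structure(6))
    count = 0
    if n > 0:
        centroids = ndimage.center_of_mass(cell_seg.astype_bool(), labels, range(1, n + 1))
        for c in centroids:
            idx = tuple(int(round(x)) for x in c)
            if effective[idx]:
                count += 1
    volume_mm3 = n_eff * cluster.voxel_volume_mm3
    return count / volume_mm3


def validate_cluster(
    values_A: Sequence[float],
    values_B: Sequence[float],
    direction: str,
    alpha: float = 0.05,
):
    """Unpaired pooled-variance one-tailed t-test in the stated direction.

    Returns (t, p_one_tailed, valid). Degenerate zero-variance data: equal
    means give p = 1; unequal means give p = 0 when the difference lies in
    the tested direction, 1 otherwise.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}, got {direction!r}")
    a = np.asarray(values_A, dtype=float)
    b = np.asarray(values_B, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")
    pooled_ss = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    diff = a.mean() - b.mean()
    if pooled_ss == 0:
        if diff == 0:
            t, p = 0.0, 1.0
        else:
            in_direction = diff > 0 if direction == "A>B" else diff < 0
            t = np.inf if diff > 0 else -np.inf
            p = 0.0 if in_direction else 1.0
        return t, p, p < alpha
    alternative = "greater" if direction == "A>B" else "less"
    res = stats.ttest_ind(a, b, equal_var=True, alternative=alternative)
    t, p = float(res.statistic), float(res.pvalue)
    return t, p, p < alpha


def validate_all(
    clusters: ClusterMap,
    subjects: Sequence[SubjectData],
    metric: str = "label_density",
    alpha: float = 0.05,
    restriction: Optional[BinaryMask] = None,
) -> pd.DataFrame:
    """Validate every cluster against per-subject tissue-space segmentations.

    Each cluster is warped to each subject's native grid (nearest-neighbour),
    the planned metric is measured per subject, and an unpaired one-tailed
    t-test is run in the direction of the cluster's voxel-wise sign
    (positive sign = A>B). Subjects without a segmentation are excluded with
    a warning; a cluster with < 2 remaining subjects in either group is
    marked untestable (valid=False, p=NaN).

    Returns one row per cluster: cluster_id, metric, n_A, n_B, mean_A,
    mean_B, direction, t, p, valid, volume_mm3.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    rows = []
    usable = [s for s in subjects if s.segmentation is not None]
    for s in subjects:
        if s.segmentation is None:
            logger.warning("subject %s has no segmentation; excluded from validation", s.subject_id)
    sign_of = dict(zip(clusters.table["cluster_id"], clusters.table["sign"]))
    for cid in clusters.cluster_ids:
        direction = "A>B" if sign_of[cid] >= 0 else "B>A"
        vals: Dict[str, float] = {}
        volumes = []
        for s in usable:
            t = s.transform if s.transform is not None else AffineTransform.identity()
            masks = warp_clusters_to_tissue(
                clusters.labels, clusters.voxel_size_um, t, s.grid, cluster_ids=[cid]
            )
            cl_mask = masks[cid]
            if cl_mask.n_voxels == 0:
                logger.warning(
                    "cluster %d maps to an empty region for subject %s", cid, s.subject_id
                )
                continue
            volumes.append(cl_mask.volume_mm3)
            if metric == "label_density":
                vals[s.subject_id] = label_density(s.segmentation, cl_mask)
            else:
                vals[s.subject_id] = cell_density(s.segmentation, cl_mask, restriction)
        a = [v for sid, v in vals.items() if _group(usable, sid) == "A"]
        b = [v for sid, v in vals.items() if _group(usable, sid) == "B"]
        if len(a) < 2 or len(b) < 2:
            rows.append(
                dict(cluster_id=cid, metric=metric, n_A=len(a), n_B=len(b),
                     mean_A=np.mean(a) if a else np.nan, mean_B=np.mean(b) if b else np.nan,
                     direction=direction, t=np.nan, p=np.nan, valid=False,
                     untestable=True, volume_mm3=np.mean(volumes) if volumes else np.nan)
            )
            continue
        t_stat, p, valid = validate_cluster(a, b, direction, alpha)
        rows.append(
            dict(cluster_id=cid, metric=metric, n_A=len(a), n_B=len(b),
                 mean_A=float(np.mean(a)), mean_B=float(np.mean(b)),
                 direction=direction, t=t_stat, p=p, valid=valid,
                 untestable=False, volume_mm3=float(np.mean(volumes)))
        )
    return pd.DataFrame(
        rows,
        columns=["cluster_id", "metric", "n_A", "n_B", "mean_A", "mean_B",
                 "direction", "t", "p", "valid", "untestable", "volume_mm3"],
    )


def _group(subjects: Sequence[SubjectData], subject_id: str) -> str:
    return next(s.group for s in subjects if s.subject_id == subject_id)
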