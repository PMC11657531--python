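"""Regional composition of valid clusters against the atlas hierarchy.

Composition is computed by intersecting each binarized cluster with the
label volume: voxel counts per leaf region and percents of cluster volume.
A reporting rule keeps the output readable: if the top-k regions cover more
than a threshold share of the cluster, leaf-level rows are reported;
otherwise leaves are collapsed into their parent regions one hierarchy level
at a time until the criterion holds or the root is reached. The long-format
export is suitable for sunburst/ring-chart tools (inner rings = parents).
"""

from __future__ import annotations

from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .atlas import Atlas, RegionNode, validate_hierarchy
from .voxstats import ClusterMap

UNDEFINED_ID = 0  # atlas background inside a cluster is reported as "undefined"

_COLUMNS = ["cluster_id", "region_id", "region_path", "voxel_count", "percent_of_cluster"]


def _region_path(atlas: Atlas, region_id: int) -> str:
    if region_id == UNDEFINED_ID:
        return "undefined"
    return "/".join(n.abbrev for n in atlas.path_to(region_id))


def composition(
    valid_clusters: ClusterMap,
    atlas: Atlas,
    include_union: bool = True,
) -> pd.DataFrame:
    """Per-cluster (and union-of-clusters) voxel counts per leaf region.

    Returns rows (cluster_id, region_id, region_path, voxel_count,
    percent_of_cluster); cluster_id ``"all_valid"`` aggregates the union of
    all clusters. Cluster voxels on atlas background fall under "undefined"
    (region_id 0).
    """
    if valid_clusters.labels.shape != atlas.labels.shape:
        raise ValueError(
            f"cluster grid {valid_clusters.labels.shape} != atlas grid {atlas.labels.shape}"
        )
    rows: List[dict] = []
    targets: List[tuple] = [(cid, valid_clusters.labels == cid) for cid in valid_clusters.cluster_ids]
    if include_union:
        targets.append(("all_valid", valid_clusters.labels > 0))
    for cid, mask in targets:
        total = int(mask.sum())
        if total == 0:
            continue
        counts = np.bincount(atlas.labels[mask].ravel())
        for region_id in np.flatnonzero(counts):  # index 0 = atlas background
            rows.append(
                dict(
                    cluster_id=cid,
                    region_id=int(region_id),
                    region_path=_region_path(atlas, int(region_id)),
                    voxel_count=int(counts[region_id]),
                    percent_of_cluster=100.0 * counts[region_id] / total,
                )
            )
    return pd.DataFrame(rows, columns=_COLUMNS)


def collapse_regions(
    rows: pd.DataFrame,
    hierarchy: Sequence[RegionNode],
    top_k: int = 4,
    threshold_percent: float = 80.0,
) -> pd.DataFrame:
    """Collapse leaf rows into parents until the top-k share exceeds threshold.

    Applied per cluster_id. At each step: if the ``top_k`` largest rows sum
    to more than ``threshold_percent`` of the cluster, rows are reported as
    they stand; otherwise every row's region is replaced by its parent (the
    root and "undefined" stay put), counts are merged, and the rule is
    re-tested. Volume-conserving at every step. Ties in the top-k ranking are
    broken by ascending region id.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if not 0.0 < threshold_percent < 100.0:
        raise ValueError("threshold_percent must be in (0, 100)")
    by_id = validate_hierarchy(hierarchy)
    missing = set(rows["region_id"]) - set(by_id) - {UNDEFINED_ID}
    if missing:
        raise ValueError(f"rows reference regions outside the hierarchy: {sorted(missing)}")
    path_of = {rid: _path_str(by_id, rid) for rid in set(rows["region_id"])}

    out_frames = []
    for cid, grp in rows.groupby("cluster_id", sort=False):
        counts: Dict[int, int] = dict(zip(grp["region_id"], grp["voxel_count"]))
        total = sum(counts.values())
        while True:
            ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
            top_share = 100.0 * sum(c for _, c in ordered[:top_k]) / total
            if top_share > threshold_percent:
                break
            merged: Dict[int, int] = {}
            changed = False
            for rid, cnt in counts.items():
                if rid == UNDEFINED_ID or by_id[rid].parent_id is None:
                    tgt = rid
                else:
                    tgt = by_id[rid].parent_id
                    changed = True
                merged[tgt] = merged.get(tgt, 0) + cnt
            counts = merged
            if not changed:
                break  # everything already at the root
        for rid, cnt in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
            path = path_of.get(rid) or _path_str(by_id, rid)
            out_frames.append(
                dict(
                    cluster_id=cid,
                    region_id=rid,
                    region_path=path,
                    voxel_count=cnt,
                    percent_of_cluster=100.0 * cnt / total,
                )
            )
    return pd.DataFrame(out_frames, columns=_COLUMNS)


def _path_str(by_id: Dict[int, RegionNode], region_id: int) -> str:
    if region_id == UNDEFINED_ID:
        return "undefined"
    node = by_id[region_id]
    chain = [node]
    while node.parent_id is not None:
        node = by_id[node.parent_id]
        chain.append(node)
    return "/".join(n.abbrev for n in chain[::-1])


def sunburst_export(rows: pd.DataFrame, hierarchy: Sequence[RegionNode]) -> pd.DataFrame:
    """Long-format hierarchical table for ring-chart tools.

    One column per hierarchy depth (``level_0`` = root ring, deeper levels
    outward) plus ``voxel_count``; rows at shallower depth leave deeper
    columns empty. Summing voxel_count within any fully-populated level
    reproduces the cluster volume.
    """
    by_id = validate_hierarchy(hierarchy)
    max_depth = max(n.depth for n in hierarchy)
    cols = ["cluster_id"] + [f"level_{d}" for d in range(max_depth + 1)] + ["voxel_count"]
    out = []
    for _, r in rows.iterrows():
        rid = r["region_id"]
        level: Dict[str, str] = {f"level_{d}": "" for d in range(max_depth + 1)}
        if rid == UNDEFINED_ID:
            level["level_0"] = "undefined"
        else:
            node = by_id[rid]
            chain = []
            while node is not None:
                chain.append(node)
                node = by_id[node.parent_id] if node.parent_id is not None else None
            for n in chain:
                level[f"level_{n.depth}"] = n.abbrev
        out.append({"cluster_id": r["cluster_id"], **level, "voxel_count": r["voxel_count"]})
    return pd.DataFrame(out, columns=cols)
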