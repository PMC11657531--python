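"""End-to-end orchestration: simulate -> preprocess -> stats -> validate -> compose.

``analyze_channel`` is the in-memory workhorse used by tests and the
acceptance script; ``run_pipeline`` wraps it with file IO, stage toggles and
a JSON run manifest (parameters, seeds, per-stage checksums, summaries).
Seeds are hierarchical: the master seed spawns independent streams for the
phantom cohort and the permutation test so stages re-run independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import compose as compose_mod
from .atlas import Atlas
from .config import ChannelParams, PipelineConfig
from .core import BinaryMask, Volume
from .io import (
    array_checksum,
    read_atlas,
    read_manifest,
    read_volume,
    write_atlas,
    write_cohort_manifest,
    write_json,
    write_volume,
)
from .phantom import PhantomSpec, make_toy_atlas, simulate_cohort
from .preprocess import (
    apply_exclusion,
    rolling_ball_subtract,
    segment_artifacts,
    segment_feature,
)
from .validate import SubjectData, validate_all
from .voxstats import (
    ClusterMap,
    GroupDesign,
    StatMaps,
    extract_clusters,
    fdr_threshold,
    gaussian_smooth,
    permutation_ttest,
    zscore_volume,
)

logger = logging.getLogger(__name__)


def derive_seeds(master_seed: int, n: int) -> List[int]:
    """Deterministic per-stage seeds below 2**31 from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


@dataclass
class ChannelResult:
    """Everything the downstream stages and reports need for one channel."""

    stats: StatMaps
    sig_mask: BinaryMask
    adjusted_p_cutoff: float
    clusters: ClusterMap
    valid_clusters: ClusterMap
    validation: pd.DataFrame
    composition: pd.DataFrame
    collapsed: pd.DataFrame
    segmentations: Dict[str, BinaryMask]


def analyze_channel(
    cohort,
    atlas: Atlas,
    channel: str,
    params: ChannelParams,
    seed: int,
    contrast: Optional[str] = None,
) -> ChannelResult:
    """Run preprocess -> voxel stats -> validation -> composition for a channel.

    ``cohort`` is a sequence of (subject_id, group, channels, truth) tuples as
    produced by :func:`brainvox.phantom.simulate_cohort` (phantoms live in
    atlas space with identity transforms).
    """
    analysis = BinaryMask(
        atlas.analysis_mask().astype(np.uint8), atlas.voxel_size_um, "atlas"
    )
    stack: List[Volume] = []
    subjects: List[SubjectData] = []
    subject_ids, group_of = [], {}
    for sid, group, chans, _truth in cohort:
        raw = chans[channel]
        bg = rolling_ball_subtract(raw, params.rolling_ball_radius_px)
        if params.mask_artifacts:
            art = segment_artifacts(
                raw, params.artifact_quantile, params.artifact_min_elongation
            )
            bg = apply_exclusion(bg, art, mode="zero_inside")
        seg = segment_feature(bg, params.feature_threshold, params.min_feature_voxels)
        z = zscore_volume(bg, analysis)
        sm = gaussian_smooth(z, params.smooth_kernel_um)
        stack.append(sm)
        subject_ids.append(sid)
        group_of[sid] = group
        subjects.append(
            SubjectData(subject_id=sid, group=group, segmentation=seg, grid=raw.grid)
        )

    design = GroupDesign(subject_ids, group_of, contrast or params.contrast)
    stats = permutation_ttest(stack, design, analysis, n_perm=params.n_perm, seed=seed)
    sig, cutoff = fdr_threshold(stats, params.q)
    clusters = extract_clusters(
        sig, stats.t_map, params.min_cluster_voxels, params.connectivity
    )
    validation = validate_all(
        clusters, subjects, metric=params.metric, alpha=params.alpha
    )
    valid_ids = set(validation.loc[validation["valid"], "cluster_id"])
    valid_clusters = _subset_clusters(clusters, valid_ids)
    comp = compose_mod.composition(valid_clusters, atlas)
    collapsed = (
        compose_mod.collapse_regions(comp, atlas.hierarchy)
        if len(comp)
        else comp
    )
    return ChannelResult(
        stats=stats,
        sig_mask=sig,
        adjusted_p_cutoff=cutoff,
        clusters=clusters,
        valid_clusters=valid_clusters,
        validation=validation,
        composition=comp,
        collapsed=collapsed,
        segmentations={s.subject_id: s.segmentation for s in subjects},
    )


def _subset_clusters(clusters: ClusterMap, keep_ids) -> ClusterMap:
    """Cluster map restricted to ``keep_ids`` (original ids preserved)."""
    labels = np.where(np.isin(clusters.labels, list(keep_ids)), clusters.labels, 0)
    table = clusters.table[clusters.table["cluster_id"].isin(keep_ids)].reset_index(drop=True)
    return ClusterMap(
        labels=labels,
        table=table,
        connectivity=clusters.connectivity,
        voxel_size_um=clusters.voxel_size_um,
        space=clusters.space,
    )


def phantom_spec_from_config(config: PipelineConfig) -> PhantomSpec:
    ph = config.phantom
    if ph is None:
        raise ValueError("config has no phantom settings but the simulate stage is enabled")
    seeds = derive_seeds(config.seed, 2)
    if ph.effect == "null":
        dens = {"A": {"deep": 800.0, "other": 400.0}, "B": {"deep": 800.0, "other": 400.0}}
    elif ph.effect == "planted":
        dens = {"A": {"deep": 800.0, "other": 400.0}, "B": {"deep": 2400.0, "other": 400.0}}
    else:
        raise ValueError(f"unknown phantom effect {ph.effect!r}")
    return PhantomSpec(
        grid_shape=tuple(ph.grid_shape),
        voxel_size_um=ph.voxel_size_um,
        n_per_group=ph.n_per_group,
        plaque_density_per_mm3=dens,
        seed=seeds[0],
    )


def load_cohort_from_manifest(manifest_path, channels) -> list:
    """Build a cohort from a manifest CSV with ``path_<channel>`` columns."""
    df = read_manifest(manifest_path)
    cohort = []
    for r in df.itertuples():
        chans = {}
        for name in channels:
            col = f"path_{name}"
            if col not in df.columns:
                raise ValueError(f"manifest lacks column {col!r} for channel {name!r}")
            chans[name] = read_volume(
                getattr(r, col), subject_id=str(r.subject_id), channel=name
            )
        cohort.append((str(r.subject_id), str(r.group), chans, None))
    return cohort


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return (and write) the run manifest."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "seeds": {},
        "stages": {},
        "checksums": {},
    }
    seeds = derive_seeds(config.seed, 4)
    manifest["seeds"] = {"master": config.seed, "phantom": seeds[0], "stats": seeds[1]}

    if "simulate" in config.stages:
        ph = config.phantom
        atlas = make_toy_atlas(
            ph.grid_shape, ph.n_parents, ph.leaves_per_parent, ph.voxel_size_um,
            seed=ph.atlas_seed,
        )
        spec = phantom_spec_from_config(config)
        cohort = simulate_cohort(spec, atlas)
        manifest["stages"]["simulate"] = {
            "n_subjects": len(cohort),
            "grid_shape": list(ph.grid_shape),
            "effect": ph.effect,
        }
        manifest["checksums"]["atlas_labels"] = array_checksum(atlas.labels)
        if config.write_volumes:
            paths = write_atlas(out_dir / "atlas", atlas)
            rows = []
            for sid, group, chans, truth in cohort:
                row = {"subject_id": sid, "group": group}
                for name, vol in chans.items():
                    p = out_dir / "subjects" / sid / f"{name}.nii.gz"
                    write_volume(p, vol)
                    row[f"path_{name}"] = str(p)
                for name, m in truth.masks.items():
                    write_volume(out_dir / "subjects" / sid / f"truth_{name}.nii.gz", m)
                rows.append(row)
            write_cohort_manifest(out_dir / "cohort.csv", pd.DataFrame(rows))
    else:
        if not (config.manifest_path and config.atlas_labels_path and config.atlas_hierarchy_path):
            raise ValueError(
                "simulate stage disabled: manifest_path and atlas paths are required"
            )
        atlas = read_atlas(
            config.atlas_labels_path,
            config.atlas_hierarchy_path,
            config.atlas_exclusions_path,
        )
        cohort = load_cohort_from_manifest(config.manifest_path, config.channels)
        manifest["stages"]["load"] = {"n_subjects": len(cohort)}
        manifest["checksums"]["atlas_labels"] = array_checksum(atlas.labels)

    results: Dict[str, ChannelResult] = {}
    if "stats" in config.stages:
        for i, (name, params) in enumerate(sorted(config.channels.items())):
            try:
                res = analyze_channel(cohort, atlas, name, params, seed=seeds[1] + i)
            except Exception as e:
                manifest["stages"][f"stats:{name}"] = {"error": str(e)}
                write_json(out_dir / "run_manifest.json", manifest)
                raise RuntimeError(f"stats stage failed for channel {name!r}: {e}") from e
            results[name] = res
            manifest["stages"][f"stats:{name}"] = {
                "n_permutations_used": res.stats.n_permutations_used,
                "exhaustive": bool(res.stats.exhaustive),
                "adjusted_p_cutoff": res.adjusted_p_cutoff,
                "n_clusters": int(len(res.clusters.table)),
                "n_valid_clusters": int(res.validation["valid"].sum()) if len(res.validation) else 0,
            }
            manifest["checksums"][f"t_map:{name}"] = array_checksum(res.stats.t_map)
            manifest["checksums"][f"clusters:{name}"] = array_checksum(res.clusters.labels)
            res.clusters.table.to_csv(out_dir / f"{name}_clusters.csv", index=False)
            res.validation.to_csv(out_dir / f"{name}_validation.csv", index=False)
            if len(res.collapsed):
                res.collapsed.to_csv(out_dir / f"{name}_composition.csv", index=False)
                compose_mod.sunburst_export(res.collapsed, atlas.hierarchy).to_csv(
                    out_dir / f"{name}_sunburst.csv", index=False
                )
    write_json(out_dir / "run_manifest.json", manifest)
    return manifest
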