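"""Pipeline configuration: per-channel parameters and run-stage toggles.

Defaults encode the analysis settings of the workflow this package
implements: rolling-ball radius 20 px at full resolution, FDR q = 0.2 with a
400-voxel extent threshold for plaque/microglia channels (q = 0.4 / 100
voxels for TH), a 100 µm smoothing kernel, and a two-group permutation
design (18,000 permutations for full-scale whole-brain runs; 1,000 by default for desk-scale
runs). Configs round-trip losslessly through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import yaml

STAGES = ("simulate", "preprocess", "stats", "validate", "compose")


@dataclass
class ChannelParams:
    """Per-channel analysis parameters with units.

    ``rolling_ball_radius_px`` is in pixels of the image it is applied to
    (20 at full-resolution tissue pixels; ~3 px is the equivalent ball at
    25 µm atlas resolution). ``smooth_kernel_um`` is the Gaussian sigma in µm.
    """

    rolling_ball_radius_px: int = 3
    mask_artifacts: bool = True
    artifact_quantile: float = 0.995
    artifact_min_elongation: float = 3.0
    feature_threshold: float = 0.5
    min_feature_voxels: int = 1
    smooth_kernel_um: float = 100.0
    q: float = 0.2
    min_cluster_voxels: int = 400
    n_perm: int = 1000
    connectivity: int = 26
    alpha: float = 0.05
    metric: str = "label_density"
    contrast: str = "two_sided"

    def __post_init__(self):
        if not 0 < self.q < 1:
            raise ValueError("q must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_cluster_voxels < 1 or self.n_perm < 1:
            raise ValueError("min_cluster_voxels and n_perm must be >= 1")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


@dataclass
class PhantomParams:
    """Synthetic-cohort settings for the simulate stage."""

    grid_shape: tuple = (64, 64, 64)
    voxel_size_um: float = 25.0
    n_per_group: int = 4
    n_parents: int = 3
    leaves_per_parent: int = 2
    atlas_seed: int = 0
    effect: str = "planted"  # "planted" (3x deep-layer plaque excess) or "null"


@dataclass
class PipelineConfig:
    output_dir: str = "brainvox_out"
    seed: int = 0
    stages: List[str] = field(default_factory=lambda: list(STAGES))
    channels: Dict[str, ChannelParams] = field(
        default_factory=lambda: {"plaque": ChannelParams()}
    )
    phantom: Optional[PhantomParams] = field(default_factory=PhantomParams)
    # file-driven inputs (used when the simulate stage is disabled)
    manifest_path: Optional[str] = None
    atlas_labels_path: Optional[str] = None
    atlas_hierarchy_path: Optional[str] = None
    atlas_exclusions_path: Optional[str] = None
    write_volumes: bool = False
    compose_top_k: int = 4
    compose_threshold_percent: float = 80.0

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    # -- YAML round-trip ----------------------------------------------------
    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path

    def to_dict(self) -> dict:
        d = asdict(self)
        if d.get("phantom") is not None:
            d["phantom"]["grid_shape"] = list(self.phantom.grid_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("channels"):
            d["channels"] = {k: ChannelParams(**v) for k, v in d["channels"].items()}
        if d.get("phantom") is not None:
            ph = dict(d["phantom"])
            ph["grid_shape"] = tuple(ph.get("grid_shape", (64, 64, 64)))
            d["phantom"] = PhantomParams(**ph)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
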