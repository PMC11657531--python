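"""Atlas containers: a labeled volume plus an Allen-style region hierarchy.

The hierarchy is a rooted tree of regions (id, name, abbreviation, parent,
depth). Voxels carry leaf labels; parents aggregate their descendants.
An exclusion set (ventricles, olfactory bulb, undefined tissue) marks labels
that are dropped from the voxel-wise analysis mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np


@dataclass(frozen=True)
class RegionNode:
    id: int
    name: str
    abbrev: str
    parent_id: Optional[int]  # None for the root
    depth: int

    def __post_init__(self):
        if self.id <= 0:
            raise ValueError(f"region id must be a positive integer, got {self.id}")
        if self.depth < 0:
            raise ValueError(f"depth must be non-negative, got {self.depth}")


def validate_hierarchy(nodes: Sequence[RegionNode]) -> Dict[int, RegionNode]:
    """Check tree invariants and return an id -> node lookup."""
    by_id = {n.id: n for n in nodes}
    if len(by_id) != len(nodes):
        raise ValueError("region ids are not unique")
    roots = [n for n in nodes if n.parent_id is None]
    if len(roots) != 1:
        raise ValueError(f"hierarchy must have exactly one root, found {len(roots)}")
    if roots[0].depth != 0:
        raise ValueError("root must have depth 0")
    for n in nodes:
        if n.parent_id is not None:
            parent = by_id.get(n.parent_id)
            if parent is None:
                raise ValueError(f"region {n.id} references missing parent {n.parent_id}")
            if parent.depth + 1 != n.depth:
                raise ValueError(
                    f"region {n.id}: depth {n.depth} != parent depth {parent.depth} + 1"
                )
    return by_id


@dataclass
class Atlas:
    """Integer label volume + region hierarchy + exclusion label set."""

    labels: np.ndarray
    voxel_size_um: Tuple[float, float, float]
    hierarchy: List[RegionNode]
    exclusion_ids: Set[int] = field(default_factory=set)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be a 3D volume")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        vs = np.broadcast_to(np.asarray(self.voxel_size_um, dtype=float), (3,))
        if np.any(vs <= 0):
            raise ValueError("voxel_size_um must be positive")
        self.voxel_size_um = tuple(float(x) for x in vs)
        by_id = validate_hierarchy(self.hierarchy)
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(by_id)
        if missing:
            raise ValueError(f"labels present in volume but absent from hierarchy: {sorted(missing)}")
        bad_excl = set(self.exclusion_ids) - set(by_id)
        if bad_excl:
            raise ValueError(f"exclusion ids not in hierarchy: {sorted(bad_excl)}")
        self.exclusion_ids = set(int(i) for i in self.exclusion_ids)

    # -- hierarchy helpers -------------------------------------------------
    @property
    def by_id(self) -> Dict[int, RegionNode]:
        return {n.id: n for n in self.hierarchy}

    @property
    def root(self) -> RegionNode:
        return next(n for n in self.hierarchy if n.parent_id is None)

    def children_of(self, region_id: int) -> List[RegionNode]:
        return [n for n in self.hierarchy if n.parent_id == region_id]

    def leaf_ids(self) -> List[int]:
        parents = {n.parent_id for n in self.hierarchy if n.parent_id is not None}
        return [n.id for n in self.hierarchy if n.id not in parents]

    def path_to(self, region_id: int) -> List[RegionNode]:
        """Chain of nodes root -> ... -> region."""
        by_id = self.by_id
        node = by_id[region_id]
        chain = [node]
        while node.parent_id is not None:
            node = by_id[node.parent_id]
            chain.append(node)
        return chain[::-1]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_um)) * 1e-9

    def region_mask(self, region_ids) -> np.ndarray:
        """Boolean mask of voxels whose leaf label is in ``region_ids``."""
        return np.isin(self.labels, np.asarray(sorted(set(region_ids)), dtype=self.labels.dtype))

    def analysis_mask(self) -> np.ndarray:
        """Brain mask minus excluded labels (ventricles, undefined, ...)."""
        out = self.labels > 0
        if self.exclusion_ids:
            out &= ~self.region_mask(self.exclusion_ids)
        return out
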