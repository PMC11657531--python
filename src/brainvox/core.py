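"""Core in-memory containers: volumes, binary masks, and grid metadata.

Every image in the pipeline carries an explicit space tag (``tissue`` or
``atlas``) and a per-axis voxel size in micrometres. Operations that combine
images refuse mismatched grids or spaces rather than silently resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np

SPACES = ("tissue", "atlas")


def _as_voxel_size(voxel_size_um) -> Tuple[float, float, float]:
    arr = np.broadcast_to(np.asarray(voxel_size_um, dtype=float), (3,)).copy()
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError(f"voxel_size_um must be positive and finite, got {voxel_size_um!r}")
    return tuple(float(x) for x in arr)


@dataclass
class GridSpec:
    """Target sampling grid: shape, per-axis voxel size (µm), and space tag."""

    shape: Tuple[int, int, int]
    voxel_size_um: Tuple[float, float, float]
    space: str = "atlas"

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        self.voxel_size_um = _as_voxel_size(self.voxel_size_um)
        if self.space not in SPACES:
            raise ValueError(f"space must be one of {SPACES}, got {self.space!r}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_um)) * 1e-9


@dataclass
class Volume:
    """A 3D scalar image with voxel size, space tag and identity metadata."""

    data: np.ndarray
    voxel_size_um: Tuple[float, float, float] = (25.0, 25.0, 25.0)
    space: str = "atlas"
    subject_id: str = ""
    channel: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got ndim={self.data.ndim}")
        self.voxel_size_um = _as_voxel_size(self.voxel_size_um)
        if self.space not in SPACES:
            raise ValueError(f"space must be one of {SPACES}, got {self.space!r}")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.data.shape, self.voxel_size_um, self.space)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_um)) * 1e-9

    def with_data(self, data: np.ndarray, **meta) -> "Volume":
        """New Volume sharing this volume's metadata but holding ``data``."""
        out = replace(self, data=np.asarray(data))
        for k, v in meta.items():
            setattr(out, k, v)
        return out

    def require_finite(self, op: str = "operation") -> None:
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"{op}: volume contains non-finite voxels")


@dataclass
class BinaryMask:
    """A {0,1} 3D mask on the same grid as its paired Volume."""

    data: np.ndarray
    voxel_size_um: Tuple[float, float, float] = (25.0, 25.0, 25.0)
    space: str = "atlas"
    subject_id: str = ""
    channel: str = ""

    def __post_init__(self):
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"BinaryMask data must be 3D, got ndim={arr.ndim}")
        if arr.dtype != np.uint8:
            if not np.isin(np.unique(arr), (0, 1)).all():
                raise ValueError("BinaryMask values must be in {0, 1}")
            arr = arr.astype(np.uint8)
        self.data = arr
        self.voxel_size_um = _as_voxel_size(self.voxel_size_um)
        if self.space not in SPACES:
            raise ValueError(f"space must be one of {SPACES}, got {self.space!r}")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.data.shape, self.voxel_size_um, self.space)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_um)) * 1e-9

    def astype_bool(self) -> np.ndarray:
        return self.data.astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.voxel_volume_mm3


def check_same_grid(a, b, what: str = "inputs") -> None:
    """Raise if two Volume/BinaryMask objects live on different grids or spaces."""
    if a.data.shape != b.data.shape:
        raise ValueError(f"{what}: shape mismatch {a.data.shape} vs {b.data.shape}")
    if not np.allclose(a.voxel_size_um, b.voxel_size_um, atol=1e-9):
        raise ValueError(f"{what}: voxel size mismatch {a.voxel_size_um} vs {b.voxel_size_um}")
    if a.space != b.space:
        raise ValueError(f"{what}: space mismatch {a.space!r} vs {b.space!r}")
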