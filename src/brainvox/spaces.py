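"""Tissue <-> atlas coordinate transforms and resampling.

Transforms are affine maps between *physical* coordinates (µm) of the two
spaces; registration estimation is out of scope — transforms are inputs
(identity for phantoms generated directly in atlas space). The coordinate
convention is: 0-based voxel index ``i`` sits at physical position
``(i + 0.5) * voxel_size`` (voxel centres).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
from scipy import ndimage

from .core import BinaryMask, GridSpec, Volume


@dataclass
class AffineTransform:
    """Affine map x_target = matrix @ x_source + offset in physical µm."""

    matrix: np.ndarray
    offset: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.offset = np.asarray(self.offset, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.matrix)) or not np.all(np.isfinite(self.offset)):
            raise ValueError("transform must be finite")
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("transform matrix is singular")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def translation(cls, offset_um) -> "AffineTransform":
        return cls(np.eye(3), np.asarray(offset_um, dtype=float))

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(inv, -inv @ self.offset)

    def apply(self, points_um: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_um, dtype=float))
        return pts @ self.matrix.T + self.offset

    # -- plain-text serialization (4x4 homogeneous, world µm) ---------------
    def to_homogeneous(self) -> np.ndarray:
        h = np.eye(4)
        h[:3, :3] = self.matrix
        h[:3, 3] = self.offset
        return h

    @classmethod
    def from_homogeneous(cls, h: np.ndarray) -> "AffineTransform":
        h = np.asarray(h, dtype=float).reshape(4, 4)
        return cls(h[:3, :3], h[:3, 3])

    def save(self, path) -> None:
        np.savetxt(path, self.to_homogeneous())

    @classmethod
    def load(cls, path) -> "AffineTransform":
        return cls.from_homogeneous(np.loadtxt(path))


_ORDERS = {"nearest": 0, "trilinear": 1}


def warp_volume(
    v: Volume,
    t: AffineTransform,
    target_grid: GridSpec,
    order: str = "trilinear",
) -> Volume:
    """Resample ``v`` onto ``target_grid`` under the source->target map ``t``.

    Pull-back interpolation: each target voxel centre is mapped through the
    inverse transform into source voxel coordinates and sampled there
    (nearest-neighbour or trilinear). Points mapping outside the source grid
    become 0. Label/mask volumes must use ``order="nearest"``.
    """
    if order not in _ORDERS:
        raise ValueError(f"order must be one of {sorted(_ORDERS)}, got {order!r}")
    inv = t.inverse()
    vs_src = np.asarray(v.voxel_size_um, dtype=float)
    vs_tgt = np.asarray(target_grid.voxel_size_um, dtype=float)
    # i_src = (Minv @ (diag(vs_tgt) (i_tgt + 0.5)) + b_inv) / vs_src - 0.5
    A = (inv.matrix * vs_tgt[None, :]) / vs_src[:, None]
    c = (inv.matrix @ (0.5 * vs_tgt) + inv.offset) / vs_src - 0.5
    is_identity = (
        np.allclose(A, np.eye(3), atol=1e-12)
        and np.allclose(c, 0.0, atol=1e-12)
        and tuple(target_grid.shape) == v.data.shape
    )
    if is_identity:
        out = v.data.copy()
    else:
        out = ndimage.affine_transform(
            v.data.astype(float, copy=False),
            matrix=A,
            offset=c,
            output_shape=tuple(target_grid.shape),
            order=_ORDERS[order],
            mode="constant",
            cval=0.0,
            prefilter=False,
        )
        if np.issubdtype(v.data.dtype, np.integer) and order == "nearest":
            out = out.astype(v.data.dtype)
    return Volume(
        out, tuple(vs_tgt), target_grid.space, v.subject_id, v.channel
    )


def warp_clusters_to_tissue(
    cluster_labels: np.ndarray,
    cluster_voxel_size_um,
    t: AffineTransform,
    full_res_grid: GridSpec,
    cluster_ids=None,
) -> Dict[int, BinaryMask]:
    """Warp each atlas-space cluster to a subject's full-resolution tissue grid.

    ``t`` is the subject's tissue->atlas transform (as stored from
    registration); clusters travel through its inverse with nearest-neighbour
    interpolation so no labels are invented. Returns one binary mask per
    cluster id; physical volumes are available via ``BinaryMask.volume_mm3``
    on the full-resolution grid.
    """
    labels = np.asarray(cluster_labels)
    present = set(int(x) for x in np.unique(labels)) - {0}
    if cluster_ids is None:
        cluster_ids = sorted(present)
    else:
        missing = set(int(i) for i in cluster_ids) - present
        if missing:
            raise ValueError(f"cluster ids absent from map: {sorted(missing)}")
    src = Volume(labels, cluster_voxel_size_um, "atlas")
    warped = warp_volume(src, t.inverse(), full_res_grid, order="nearest")
    out = {}
    for cid in cluster_ids:
        out[int(cid)] = BinaryMask(
            (warped.data == cid).astype(np.uint8),
            full_res_grid.voxel_size_um,
            full_res_grid.space,
        )
    return out


def mirror_unilateral(labels: np.ndarray, midline_axis: int) -> np.ndarray:
    """Union a unilateral cluster map with its reflection about the grid's
    central plane on ``midline_axis`` (display only). Idempotent once applied;
    existing labels take precedence over reflected ones.
    """
    labels = np.asarray(labels)
    flipped = np.flip(labels, axis=midline_axis)
    return np.where(labels != 0, labels, flipped)
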