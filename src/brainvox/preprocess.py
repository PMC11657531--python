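"""Background subtraction, artifact masking and feature segmentation.

These are the full-resolution tissue-space steps applied to each channel
before warping to atlas space: rolling-ball background subtraction
(slice-wise grayscale opening with a disk), a deterministic rule-based
stand-in for interactive pixel classification (intensity quantile +
shape-based tube detection for capillary artifacts; threshold + size filter
for feature segmentation), masking, and block-mean downsampling.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .core import BinaryMask, Volume, check_same_grid

_CONN_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3D structuring element for 6-, 18- or 26-connectivity."""
    try:
        return _CONN_STRUCTS[int(connectivity)]
    except KeyError:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")


def rolling_ball_subtract(v: Volume, radius_px: int = 20) -> Volume:
    """Subtract a slice-wise rolling-ball background estimate.

    The background is estimated per z-slice by grayscale opening with a disk
    of ``radius_px`` pixels (erosion then dilation), the standard morphological
    equivalent of the ImageJ rolling-ball estimator, and subtracted with
    clipping at zero. Output is everywhere >= 0 and <= input.
    """
    if radius_px < 1:
        raise ValueError(f"radius_px must be >= 1, got {radius_px}")
    v.require_finite("rolling_ball_subtract")
    footprint = disk(int(radius_px))[None, :, :]  # 2D disk, applied slice-wise
    background = ndimage.grey_opening(v.data, footprint=footprint, mode="nearest")
    return v.with_data(np.clip(v.data - background, 0.0, None))


def segment_artifacts(
    v: Volume,
    intensity_quantile: float = 0.995,
    min_elongation: float = 3.0,
) -> BinaryMask:
    """Flag tube-like high-intensity components (capillaries, edges).

    Voxels above the given intensity quantile are grouped into 26-connected
    components; a component is flagged as artifact when the elongation of its
    voxel-coordinate cloud — sqrt of the ratio of the largest to the smallest
    principal variance, each regularised by the 1/12 voxel extent — is at
    least ``min_elongation``. Spherical blobs score near 1, tubes score
    roughly length/diameter.
    """
    if not 0.0 < intensity_quantile < 1.0:
        raise ValueError("intensity_quantile must be in (0, 1)")
    if min_elongation < 1.0:
        raise ValueError("min_elongation must be >= 1")
    thr = np.quantile(v.data, intensity_quantile)
    above = v.data > thr
    out = np.zeros(v.data.shape, dtype=np.uint8)
    if above.any():
        labels, n = ndimage.label(above, structure=connectivity_structure(26))
        for sl, lab in zip(ndimage.find_objects(labels), range(1, n + 1)):
            coords = np.argwhere(labels[sl] == lab) + [s.start for s in sl]
            if component_elongation(coords) >= min_elongation:
                out[tuple(coords.T)] = 1
    return BinaryMask(out, v.voxel_size_um, v.space, v.subject_id, v.channel)


def component_elongation(coords: np.ndarray) -> float:
    """Principal-axis elongation of a voxel coordinate cloud.

    sqrt((lam_max + 1/12) / (lam_min + 1/12)) of the coordinate covariance;
    the 1/12 term is the variance of a unit voxel, preventing zero-thickness
    degeneracies for flat or single-voxel components.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 2:
        return 1.0
    cov = np.cov(coords.T)
    eig = np.sort(np.linalg.eigvalsh(cov))
    return float(np.sqrt((eig[-1] + 1.0 / 12.0) / (eig[0] + 1.0 / 12.0)))


def apply_exclusion(v: Volume, mask: BinaryMask, mode: str = "zero_inside") -> Volume:
    """Zero out masked voxels (artifacts) or keep only masked voxels.

    ``zero_inside`` sets voxels under the mask to exactly 0 (artifact
    removal); ``zero_outside`` keeps only voxels under the mask (e.g.
    preserving reactive-microglia signal). All other voxels are bit-identical
    to the input. Idempotent.
    """
    check_same_grid(v, mask, "apply_exclusion")
    if mode not in ("zero_inside", "zero_outside"):
        raise ValueError(f"mode must be zero_inside or zero_outside, got {mode!r}")
    keep = mask.data == 0 if mode == "zero_inside" else mask.data != 0
    return v.with_data(np.where(keep, v.data, 0.0))


def segment_feature(v: Volume, threshold: float, min_object_voxels: int = 1) -> BinaryMask:
    """Threshold + size-filter segmentation of a background-subtracted channel.

    Voxels strictly above ``threshold`` form the candidate mask; 26-connected
    components smaller than ``min_object_voxels`` are removed.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if min_object_voxels < 1:
        raise ValueError("min_object_voxels must be >= 1")
    mask = v.data > threshold
    if min_object_voxels > 1 and mask.any():
        labels, n = ndimage.label(mask, structure=connectivity_structure(26))
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < min_object_voxels)
        mask &= ~np.isin(labels, small[small > 0])
    return BinaryMask(
        mask.astype(np.uint8), v.voxel_size_um, v.space, v.subject_id, v.channel
    )


def downsample(v: Volume, factor: int) -> Volume:
    """Block-mean downsample by an integer factor on each axis.

    Edge blocks are completed by edge replication so partial blocks average
    real data only. Voxel size scales by the factor.
    """
    if factor < 1:
        raise ValueError(f"factor must be >= 1, got {factor}")
    if factor == 1:
        return v.with_data(v.data.copy())
    if any(factor > s for s in v.data.shape):
        raise ValueError(f"factor {factor} exceeds an axis of shape {v.data.shape}")
    pad = [(0, (-s) % factor) for s in v.data.shape]
    padded = np.pad(v.data, pad, mode="edge")
    sh = padded.shape
    blocks = padded.reshape(
        sh[0] // factor, factor, sh[1] // factor, factor, sh[2] // factor, factor
    )
    out = blocks.mean(axis=(1, 3, 5))
    new_vs = tuple(x * factor for x in v.voxel_size_um)
    result = v.with_data(out)
    result.voxel_size_um = new_vs
    return result
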