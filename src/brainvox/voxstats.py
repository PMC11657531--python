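"""Atlas-space voxel-wise two-group inference.

Per-subject z-scoring inside a brain mask, Gaussian smoothing, a two-sample
permutation t-test (exhaustive over all balanced label assignments when
feasible, Monte-Carlo otherwise), Benjamini–Hochberg FDR over in-mask voxels,
and cluster extraction with an extent threshold.

The permutation scheme permutes group labels (the correct exchangeable unit
for a two-group design). With :math:`m` enumerated assignments the p-value at
a voxel is the fraction of assignments whose statistic is at least as extreme
as the observed one (the observed assignment is among them); with sampled
permutations the add-one estimator :math:`(b+1)/(m+1)` is used, so p-values
are valid and never zero.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from statsmodels.stats.multitest import multipletests

from .core import BinaryMask, Volume, check_same_grid
from .preprocess import connectivity_structure

CONTRASTS = ("A>B", "B>A", "two_sided")


@dataclass
class GroupDesign:
    """Two-group design: subject order, group membership, contrast."""

    subject_ids: List[str]
    group_of: Dict[str, str]
    contrast: str = "two_sided"

    def __post_init__(self):
        if self.contrast not in CONTRASTS:
            raise ValueError(f"contrast must be one of {CONTRASTS}, got {self.contrast!r}")
        missing = [s for s in self.subject_ids if s not in self.group_of]
        if missing:
            raise ValueError(f"subjects without a group assignment: {missing}")
        bad = {g for g in self.group_of.values() if g not in ("A", "B")}
        if bad:
            raise ValueError(f"groups must be A or B, got {sorted(bad)}")
        n_a = sum(self.group_of[s] == "A" for s in self.subject_ids)
        n_b = len(self.subject_ids) - n_a
        if n_a < 2 or n_b < 2:
            raise ValueError(f"need >= 2 subjects per group, got {n_a} A and {n_b} B")

    @property
    def labels(self) -> np.ndarray:
        """Boolean vector, True where the subject is in group A."""
        return np.array([self.group_of[s] == "A" for s in self.subject_ids])


@dataclass
class StatMaps:
    t_map: np.ndarray
    p_map: np.ndarray
    analysis_mask: BinaryMask
    n_permutations_used: int
    exhaustive: bool
    zero_variance_mask: Optional[np.ndarray] = None


@dataclass
class ClusterMap:
    """Significant-voxel clusters: labels 1..K ordered by descending size."""

    labels: np.ndarray
    table: pd.DataFrame  # cluster_id, n_voxels, sign, peak_abs_t
    connectivity: int
    voxel_size_um: Tuple[float, float, float] = (25.0, 25.0, 25.0)
    space: str = "atlas"

    @property
    def cluster_ids(self) -> List[int]:
        return [int(i) for i in self.table["cluster_id"]]

    def mask_of(self, cluster_id: int) -> np.ndarray:
        return self.labels == cluster_id

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_um)) * 1e-9


# ---------------------------------------------------------------------------
# z-scoring & smoothing
# ---------------------------------------------------------------------------

def zscore_volume(v: Volume, analysis_mask: BinaryMask) -> Volume:
    """Z-score a volume using the mask-restricted mean and population SD.

    Outside the mask the output is 0. A degenerate (constant-in-mask) image
    is rejected.
    """
    check_same_grid(v, analysis_mask, "zscore_volume")
    inside = analysis_mask.astype_bool()
    if inside.sum() < 2:
        raise ValueError("analysis mask must contain >= 2 voxels")
    vals = v.data[inside]
    mu = vals.mean()
    sd = vals.std(ddof=0)
    if sd == 0:
        raise ValueError("degenerate image: zero variance inside analysis mask")
    out = np.zeros_like(v.data, dtype=float)
    out[inside] = (vals - mu) / sd
    return v.with_data(out)


def gaussian_smooth(v: Volume, kernel_um: float) -> Volume:
    """Gaussian smoothing with sigma = ``kernel_um`` per axis (anisotropy-aware).

    Reflection boundary handling keeps constant images constant and preserves
    interior intensity.
    """
    if not (kernel_um > 0):
        raise ValueError(f"kernel_um must be > 0, got {kernel_um}")
    v.require_finite("gaussian_smooth")
    sigma_vox = [kernel_um / s for s in v.voxel_size_um]
    out = ndimage.gaussian_filter(v.data.astype(float), sigma=sigma_vox, mode="reflect")
    return v.with_data(out)


# ---------------------------------------------------------------------------
# permutation t-test
# ---------------------------------------------------------------------------

def _t_for_assignments(X: np.ndarray, assign: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t for each row of boolean ``assign``.

    ``X`` is (n_subjects, V); ``assign`` is (m, n_subjects) with True marking
    group A. Returns (m, V). Voxels with zero pooled variance get t = 0 when
    the mean difference is also 0, else +/- inf.
    """
    n = X.shape[0]
    nA = int(assign[0].sum())
    nB = n - nA
    G = assign.astype(float)
    S = X.sum(axis=0)
    S2 = (X**2).sum(axis=0)
    SA = G @ X
    SA2 = G @ (X**2)
    SB = S - SA
    SB2 = S2 - SA2
    mA = SA / nA
    mB = SB / nB
    ssA = SA2 - SA**2 / nA
    ssB = SB2 - SB**2 / nB
    sp2 = (ssA + ssB) / (n - 2)
    sp2 = np.maximum(sp2, 0.0)  # guard tiny negative round-off
    denom = np.sqrt(sp2 * (1.0 / nA + 1.0 / nB))
    diff = mA - mB
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    signed_inf = np.where(diff > 0, np.inf, -np.inf)
    t = np.where(denom == 0, np.where(diff == 0, 0.0, signed_inf), t)
    return t


def balanced_assignments(labels: np.ndarray) -> np.ndarray:
    """All distinct relabelings preserving the observed group sizes.

    Returns (C(n, nA), n) boolean; the first row is the observed assignment.
    """
    n = labels.size
    idx_a = int(labels.sum())
    rows = []
    for combo in itertools.combinations(range(n), idx_a):
        row = np.zeros(n, dtype=bool)
        row[list(combo)] = True
        rows.append(row)
    rows = np.array(rows)
    obs = np.flatnonzero((rows == labels[None, :]).all(axis=1))[0]
    if obs != 0:  # put the observed assignment first
        rows[[0, obs]] = rows[[obs, 0]]
    return rows


def permutation_ttest(
    stack: Sequence[Volume],
    design: GroupDesign,
    analysis_mask: BinaryMask,
    n_perm: int = 1000,
    seed: int = 0,
    chunk: int = 256,
) -> StatMaps:
    """Voxel-wise two-sample permutation t-test over a subject stack.

    If the number of distinct balanced label assignments is <= ``n_perm`` the
    null is enumerated exhaustively (``exhaustive=True``); otherwise
    ``n_perm`` random relabelings are drawn with ``seed``. The contrast in
    ``design`` selects two-sided (|t|) or directed comparison. Voxels with
    zero pooled variance in the observed data are flagged and given p = 1.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if len(stack) != len(design.subject_ids):
        raise ValueError("stack length does not match design")
    for vol in stack:
        check_same_grid(vol, analysis_mask, "permutation_ttest")

    inside = analysis_mask.astype_bool()
    flat_idx = np.flatnonzero(inside.ravel())
    X = np.stack([vol.data.ravel()[flat_idx] for vol in stack])
    labels = design.labels
    n = labels.size
    nA = int(labels.sum())
    n_total = math.comb(n, nA)
    exhaustive = n_total <= n_perm

    if exhaustive:
        assign = balanced_assignments(labels)
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
        assign = labels[perms]
        assign = np.vstack([labels, assign])  # observed first, not counted in m

    t_all = np.empty((assign.shape[0], X.shape[1]))
    for start in range(0, assign.shape[0], chunk):
        t_all[start : start + chunk] = _t_for_assignments(X, assign[start : start + chunk])
    t_obs = t_all[0]
    t_null = t_all if exhaustive else t_all[1:]
    m = t_null.shape[0]

    eps = 1e-12
    if design.contrast == "two_sided":
        b = (np.abs(t_null) >= np.abs(t_obs)[None, :] - eps).sum(axis=0)
    elif design.contrast == "A>B":
        b = (t_null >= t_obs[None, :] - eps).sum(axis=0)
    else:  # B>A
        b = (t_null <= t_obs[None, :] + eps).sum(axis=0)
    if exhaustive:
        p = b / m
    else:
        p = (b + 1) / (m + 1)

    zero_var = ~np.isfinite(t_obs) | (np.abs(t_obs) == 0) & (X.std(axis=0) == 0)
    p = np.where(zero_var, 1.0, p)
    t_obs = np.where(np.isfinite(t_obs), t_obs, 0.0)

    shape = analysis_mask.data.shape
    t_map = np.zeros(shape)
    p_map = np.ones(shape)
    t_map.ravel()[flat_idx] = t_obs
    p_map.ravel()[flat_idx] = p
    zv_map = np.zeros(shape, dtype=bool)
    zv_map.ravel()[flat_idx] = zero_var
    return StatMaps(
        t_map=t_map,
        p_map=p_map,
        analysis_mask=analysis_mask,
        n_permutations_used=m,
        exhaustive=exhaustive,
        zero_variance_mask=zv_map,
    )


# ---------------------------------------------------------------------------
# FDR & clusters
# ---------------------------------------------------------------------------

def fdr_threshold(maps: StatMaps, q: float = 0.2) -> Tuple[BinaryMask, float]:
    """Benjamini–Hochberg step-up over all in-mask voxels.

    Returns the mask of significant voxels and the realized p-value cutoff
    (the largest p passing the step-up rule, 0.0 if none pass).
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must be in (0, 1), got {q}")
    inside = maps.analysis_mask.astype_bool()
    p = maps.p_map[inside]
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")[:4]
    cutoff = float(p[reject].max()) if reject.any() else 0.0
    sig = np.zeros(maps.p_map.shape, dtype=np.uint8)
    if cutoff > 0:
        sig[inside] = (p <= cutoff).astype(np.uint8)
    am = maps.analysis_mask
    return BinaryMask(sig, am.voxel_size_um, am.space), cutoff


def extract_clusters(
    sig_mask: BinaryMask,
    t_map: np.ndarray,
    min_voxels: int = 400,
    connectivity: int = 26,
) -> ClusterMap:
    """Sign-split connected components of the significant mask with extent
    thresholding.

    Positive-t and negative-t significant voxels are clustered separately
    (adjacent opposite-sign effects are distinct findings and must not merge
    into one component). Components smaller than ``min_voxels`` are
    discarded; survivors are labeled 1..K by descending voxel count (ties
    broken by sign then original label).
    """
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    t_arr = np.asarray(t_map)
    if sig_mask.data.shape != t_arr.shape:
        raise ValueError("sig_mask and t_map shapes differ")
    structure = connectivity_structure(connectivity)
    sig = sig_mask.astype_bool()
    rows = []
    comps = {}
    for sign, sel_mask in ((1, sig & (t_arr >= 0)), (-1, sig & (t_arr < 0))):
        comp, n = ndimage.label(sel_mask, structure=structure)
        comps[sign] = comp
        if n == 0:
            continue
        sizes = np.bincount(comp.ravel())
        for lab in range(1, n + 1):
            if sizes[lab] < min_voxels:
                continue
            tvals = t_arr[comp == lab]
            rows.append(
                {
                    "sign": sign,
                    "orig": lab,
                    "n_voxels": int(sizes[lab]),
                    "peak_abs_t": float(np.abs(tvals).max()),
                }
            )
    rows.sort(key=lambda r: (-r["n_voxels"], -r["sign"], r["orig"]))
    labels_out = np.zeros(sig.shape, dtype=np.int32)
    table_rows = []
    for new_id, r in enumerate(rows, start=1):
        labels_out[comps[r["sign"]] == r["orig"]] = new_id
        table_rows.append(
            {
                "cluster_id": new_id,
                "n_voxels": r["n_voxels"],
                "sign": r["sign"],
                "peak_abs_t": r["peak_abs_t"],
            }
        )
    table = pd.DataFrame(
        table_rows, columns=["cluster_id", "n_voxels", "sign", "peak_abs_t"]
    )
    return ClusterMap(
        labels=labels_out,
        table=table,
        connectivity=int(connectivity),
        voxel_size_um=sig_mask.voxel_size_um,
        space=sig_mask.space,
    )
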