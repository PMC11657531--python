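"""Synthetic cleared-hemisphere phantoms with a toy atlas and known ground truth.

The generator emulates the statistical structure of a two-group (e.g.
amyloidosis model vs. control) light-sheet experiment:

* a ``plaque`` channel of Poisson-placed Gaussian blobs whose density is
  group- and region-dependent (enriched in designated "deep layer" leaves),
* a ``microglia`` channel of baseline speckle with bright halos around plaque
  centres (reactive microglia aggregating at plaques),
* a ``th`` channel of tubular fibre tracts with group-dependent intensity plus
  spherical somata in designated soma regions (fibre loss and focal cell loss),
* capillary-like high-intensity tube artifacts added to the plaque and
  microglia channels, and
* an ``autofluorescence`` channel carrying only anatomy.

Every placed object is recorded in ground-truth masks *before* noise, with the
mask defined as the analytic profile above its half-maximum, so truth is
unambiguous and resolution-independent. All outputs are pure functions of
(spec, seeds). Phantoms are generated directly in atlas space (per-subject
transform = identity) so the downstream pipeline can be exercised without
registration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .atlas import Atlas, RegionNode
from .core import BinaryMask, Volume

CHANNELS = ("autofluorescence", "plaque", "microglia", "th")
GROUPS = ("A", "B")

# Gaussian blob: profile exp(-d^2 / 2 sigma^2) crosses half-maximum at
# d = sigma * sqrt(2 ln 2); we parameterise blobs by that half-max radius.
_HALFMAX = math.sqrt(2.0 * math.log(2.0))


# ---------------------------------------------------------------------------
# toy atlas
# ---------------------------------------------------------------------------

def make_toy_atlas(
    grid_shape: Sequence[int],
    n_parents: int,
    leaves_per_parent: int,
    voxel_size_um: float = 25.0,
    seed: int = 0,
) -> Atlas:
    """Build a toy hierarchical atlas on an ellipsoidal "hemisphere".

    The foreground ellipsoid is partitioned into contiguous leaf regions
    (equal-occupancy slabs along axis 0 for parents, axis 1 for leaves within
    each parent). A small "ventricle" sphere near the centre and an
    "undefined" sphere near the caudal pole are carved out as exclusion
    leaves parented directly under the root.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    if len(grid_shape) != 3 or any(s < 16 for s in grid_shape):
        raise ValueError(f"grid_shape axes must all be >= 16, got {grid_shape}")
    if n_parents < 2:
        raise ValueError(f"n_parents must be >= 2, got {n_parents}")
    if leaves_per_parent < 1:
        raise ValueError(f"leaves_per_parent must be >= 1, got {leaves_per_parent}")

    rng = np.random.default_rng(seed)
    shape = np.array(grid_shape, dtype=float)
    center = (shape - 1) / 2.0
    semi = 0.44 * shape

    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in grid_shape), indexing="ij")
    r2 = (
        ((zz - center[0]) / semi[0]) ** 2
        + ((yy - center[1]) / semi[1]) ** 2
        + ((xx - center[2]) / semi[2]) ** 2
    )
    brain = r2 <= 1.0

    labels = np.zeros(grid_shape, dtype=np.int32)

    root_id = 1
    parent_ids = list(range(2, 2 + n_parents))
    leaf_id0 = 2 + n_parents
    hierarchy: List[RegionNode] = [RegionNode(root_id, "root", "ROOT", None, 0)]

    # parents: contiguous slabs along axis 0 with equal foreground occupancy
    fg0 = zz[brain]
    edges0 = np.quantile(fg0, np.linspace(0, 1, n_parents + 1))
    edges0[0] -= 1.0
    next_leaf = leaf_id0
    for pi, pid in enumerate(parent_ids):
        hierarchy.append(RegionNode(pid, f"parent_{pi}", f"P{pi}", root_id, 1))
        slab = brain & (zz > edges0[pi]) & (zz <= edges0[pi + 1])
        fg1 = yy[slab]
        if fg1.size == 0:
            raise ValueError("degenerate atlas partition; increase grid size")
        edges1 = np.quantile(fg1, np.linspace(0, 1, leaves_per_parent + 1))
        edges1[0] -= 1.0
        for li in range(leaves_per_parent):
            lid = next_leaf
            next_leaf += 1
            hierarchy.append(
                RegionNode(lid, f"leaf_{pi}_{li}", f"P{pi}L{li}", pid, 2)
            )
            sel = slab & (yy > edges1[li]) & (yy <= edges1[li + 1])
            labels[sel] = lid

    # exclusion leaves: ventricle near the centre, undefined near one pole
    vent_id, undef_id = next_leaf, next_leaf + 1
    hierarchy.append(RegionNode(vent_id, "ventricle", "VENT", root_id, 1))
    hierarchy.append(RegionNode(undef_id, "undefined", "UNDEF", root_id, 1))

    vent_center = center + rng.uniform(-1.5, 1.5, size=3)
    vent_r = max(2.0, 0.08 * float(shape.min()))
    d2 = (zz - vent_center[0]) ** 2 + (yy - vent_center[1]) ** 2 + (xx - vent_center[2]) ** 2
    labels[brain & (d2 <= vent_r**2)] = vent_id

    undef_center = center.copy()
    undef_center[0] = center[0] + 0.7 * semi[0]
    d2 = (zz - undef_center[0]) ** 2 + (yy - undef_center[1]) ** 2 + (xx - undef_center[2]) ** 2
    labels[brain & (d2 <= vent_r**2)] = undef_id

    return Atlas(
        labels=labels,
        voxel_size_um=(voxel_size_um,) * 3,
        hierarchy=hierarchy,
        exclusion_ids={vent_id, undef_id},
    )


def deep_layer_leaves(atlas: Atlas) -> FrozenSet[int]:
    """Designated "deep layer" leaves: the lowest-id leaf of each parent.

    These are the regions in which plaque density is enriched (and where a
    planted group effect lives under the default spec).
    """
    out = set()
    for parent in sorted(atlas.children_of(atlas.root.id), key=lambda n: n.id):
        kids = [n for n in atlas.children_of(parent.id) if n.id not in atlas.exclusion_ids]
        if kids:
            out.add(min(k.id for k in kids))
    return frozenset(out)


def soma_region_leaves(atlas: Atlas) -> FrozenSet[int]:
    """Designated soma-bearing leaf: the highest-id non-excluded leaf."""
    leaves = [i for i in atlas.leaf_ids() if i not in atlas.exclusion_ids]
    return frozenset({max(leaves)}) if leaves else frozenset()


# ---------------------------------------------------------------------------
# phantom spec & truth
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Parameters of a two-group synthetic cohort.

    Group effects are encoded *only* through the group-indexed fields
    (``plaque_density_per_mm3``, ``fiber_intensity``, ``soma_count``); with
    equal values per group the two groups are identical in law.
    Densities are per region class: "deep" for designated deep-layer leaves,
    "other" for every other non-excluded leaf.
    """

    grid_shape: Tuple[int, int, int] = (64, 64, 64)
    voxel_size_um: float = 25.0
    n_per_group: int = 4
    plaque_density_per_mm3: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "A": {"deep": 800.0, "other": 400.0},
            "B": {"deep": 2400.0, "other": 400.0},
        }
    )
    plaque_radius_um: Tuple[float, float] = (20.0, 40.0)
    microglia_halo_gain: float = 3.0
    microglia_halo_radius_um: float = 75.0
    fiber_intensity: Mapping[str, float] = field(
        default_factory=lambda: {"A": 1.0, "B": 1.0}
    )
    soma_count: Mapping[str, int] = field(default_factory=lambda: {"A": 30, "B": 30})
    soma_radius_um: float = 20.0
    n_fiber_tracts: int = 6
    artifact_tube_count: int = 2
    noise_sd: float = 0.05
    seed: int = 0
    # per-leaf density multiplier table (applied on top of the class density)
    region_multiplier: Mapping[int, float] = field(default_factory=dict)
    # resolved against the atlas at simulation time when left as None
    deep_region_ids: Optional[FrozenSet[int]] = None
    soma_region_ids: Optional[FrozenSet[int]] = None

    def __post_init__(self):
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        for g in GROUPS:
            for cls in ("deep", "other"):
                d = self.plaque_density_per_mm3[g][cls]
                if not np.isfinite(d) or d < 0:
                    raise ValueError(f"plaque density [{g}][{cls}] must be finite and >= 0")
        if self.microglia_halo_gain < 1:
            raise ValueError("microglia_halo_gain must be >= 1")
        lo, hi = self.plaque_radius_um
        if not (0 < lo <= hi):
            raise ValueError("plaque_radius_um must be a positive (lo, hi) range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.artifact_tube_count < 0:
            raise ValueError("artifact_tube_count must be >= 0")


@dataclass
class PhantomTruth:
    """Ground truth for one synthetic subject: noise-free object masks."""

    masks: Dict[str, BinaryMask]  # plaque, reactive_microglia, fiber, soma, artifact
    planted_effect_region_ids: Set[int]
    group: str


# ---------------------------------------------------------------------------
# analytic rasterisers
# ---------------------------------------------------------------------------

def _stamp_blob(data, truth, center_vox, radius_um, voxel_size_um, amplitude):
    """Add a Gaussian blob (half-max radius ``radius_um``) at a voxel position."""
    vs = np.asarray(voxel_size_um, dtype=float)
    sigma_um = radius_um / _HALFMAX
    ext = np.ceil(3.5 * sigma_um / vs).astype(int)
    lo = np.maximum(np.round(center_vox).astype(int) - ext, 0)
    hi = np.minimum(np.round(center_vox).astype(int) + ext + 1, data.shape)
    if np.any(lo >= hi):
        return
    coords = [np.arange(lo[a], hi[a]) for a in range(3)]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")
    d2 = (
        ((zz - center_vox[0]) * vs[0]) ** 2
        + ((yy - center_vox[1]) * vs[1]) ** 2
        + ((xx - center_vox[2]) * vs[2]) ** 2
    )
    prof = amplitude * np.exp(-d2 / (2.0 * sigma_um**2))
    sl = tuple(slice(lo[a], hi[a]) for a in range(3))
    data[sl] += prof
    truth[sl] |= d2 <= radius_um**2


def _stamp_capsule(data, truth, p0_vox, p1_vox, radius_um, voxel_size_um, amplitude):
    """Add a capsule (tube with hemispherical caps) between two voxel points."""
    vs = np.asarray(voxel_size_um, dtype=float)
    sigma_um = radius_um / _HALFMAX
    ext = np.ceil(3.5 * sigma_um / vs).astype(int)
    lo = np.maximum(np.floor(np.minimum(p0_vox, p1_vox)).astype(int) - ext, 0)
    hi = np.minimum(np.ceil(np.maximum(p0_vox, p1_vox)).astype(int) + ext + 1, data.shape)
    if np.any(lo >= hi):
        return
    coords = [np.arange(lo[a], hi[a]) for a in range(3)]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")
    pts = np.stack([zz * vs[0], yy * vs[1], xx * vs[2]], axis=-1)
    a = np.asarray(p0_vox) * vs
    b = np.asarray(p1_vox) * vs
    ab = b - a
    denom = float(ab @ ab)
    t = ((pts - a) @ ab) / denom if denom > 0 else np.zeros(pts.shape[:-1])
    t = np.clip(t, 0.0, 1.0)
    closest = a + t[..., None] * ab
    d2 = np.sum((pts - closest) ** 2, axis=-1)
    prof = amplitude * np.exp(-d2 / (2.0 * sigma_um**2))
    sl = tuple(slice(lo[a_], hi[a_]) for a_ in range(3))
    data[sl] = np.maximum(data[sl], prof)
    truth[sl] |= d2 <= radius_um**2


# ---------------------------------------------------------------------------
# subject & cohort simulation
# ---------------------------------------------------------------------------

def _leaf_classes(spec: PhantomSpec, atlas: Atlas) -> Dict[int, str]:
    deep = spec.deep_region_ids if spec.deep_region_ids is not None else deep_layer_leaves(atlas)
    classes = {}
    for lid in atlas.leaf_ids():
        if lid in atlas.exclusion_ids:
            continue
        classes[lid] = "deep" if lid in deep else "other"
    return classes


def planted_effect_regions(spec: PhantomSpec, atlas: Atlas) -> Set[int]:
    """Leaves in which the two groups differ in expectation."""
    out: Set[int] = set()
    classes = _leaf_classes(spec, atlas)
    for lid, cls in classes.items():
        if spec.plaque_density_per_mm3["A"][cls] != spec.plaque_density_per_mm3["B"][cls]:
            out.add(lid)
    if spec.soma_count["A"] != spec.soma_count["B"]:
        soma = spec.soma_region_ids if spec.soma_region_ids is not None else soma_region_leaves(atlas)
        out |= set(soma)
    return out


def simulate_subject(
    spec: PhantomSpec,
    atlas: Atlas,
    group: str,
    subject_seed: int,
    subject_id: str = "",
    channels: Sequence[str] = CHANNELS,
) -> Tuple[Dict[str, Volume], PhantomTruth]:
    """Render one synthetic subject's channels and its ground truth.

    ``channels`` selects which channels are returned; rendering and random
    draws are identical regardless of the selection, so any subset of the
    returned channels is bit-identical to the full render.
    """
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}, got {group!r}")
    if tuple(atlas.labels.shape) != spec.grid_shape:
        raise ValueError(
            f"atlas grid {atlas.labels.shape} does not match spec grid {spec.grid_shape}"
        )
    unknown = set(channels) - set(CHANNELS)
    if unknown:
        raise ValueError(f"unknown channels: {sorted(unknown)}")

    vs = np.asarray(atlas.voxel_size_um, dtype=float)
    voxvol_mm3 = atlas.voxel_volume_mm3
    shape = spec.grid_shape
    brain = atlas.labels > 0

    # independent streams per signal class so channel selection cannot
    # perturb the draws of another channel
    ss = np.random.SeedSequence(subject_seed)
    rng_plaque, rng_micro, rng_th, rng_art, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    data = {name: np.zeros(shape, dtype=np.float64) for name in CHANNELS}
    truth = {
        name: np.zeros(shape, dtype=bool)
        for name in ("plaque", "reactive_microglia", "fiber", "soma", "artifact")
    }

    # --- plaques ------------------------------------------------------------
    classes = _leaf_classes(spec, atlas)
    plaque_centers: List[np.ndarray] = []
    for lid in sorted(classes):
        density = spec.plaque_density_per_mm3[group][classes[lid]]
        density *= spec.region_multiplier.get(lid, 1.0)
        flat = np.flatnonzero(atlas.labels == lid)
        lam = density * flat.size * voxvol_mm3
        n = int(rng_plaque.poisson(lam))
        if n == 0:
            continue
        picks = rng_plaque.choice(flat, size=n, replace=True)
        jitter = rng_plaque.uniform(-0.5, 0.5, size=(n, 3))
        radii = rng_plaque.uniform(*spec.plaque_radius_um, size=n)
        centers = np.stack(np.unravel_index(picks, shape), axis=1) + jitter
        for c, r in zip(centers, radii):
            plaque_centers.append(c)
            _stamp_blob(data["plaque"], truth["plaque"], c, r, vs, amplitude=1.0)

    # --- microglia: speckle baseline + halos around plaque centres ---------
    halo = np.zeros(shape, dtype=bool)
    for c in plaque_centers:
        _truth_ball(halo, c, spec.microglia_halo_radius_um, vs)
    halo &= brain
    truth["reactive_microglia"] = halo
    speckle = rng_micro.gamma(shape=2.0, scale=0.1, size=shape)
    base = np.where(brain, 0.2 + speckle, 0.0)
    data["microglia"] = np.where(halo, spec.microglia_halo_gain * base, base)

    # --- TH: fibre tracts + somata ------------------------------------------
    fi = float(spec.fiber_intensity[group])
    starts = rng_th.uniform(0.25, 0.75, size=(spec.n_fiber_tracts, 3)) * np.array(shape)
    dirs = rng_th.normal(size=(spec.n_fiber_tracts, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    lengths = rng_th.uniform(0.3, 0.6, size=spec.n_fiber_tracts) * min(shape)
    for s, d, L in zip(starts, dirs, lengths):
        p0, p1 = s - d * L / 2, s + d * L / 2
        _stamp_capsule(data["th"], truth["fiber"], p0, p1, 30.0, vs, amplitude=fi)
    soma_ids = spec.soma_region_ids if spec.soma_region_ids is not None else soma_region_leaves(atlas)
    soma_flat = np.flatnonzero(atlas.region_mask(soma_ids)) if soma_ids else np.array([], dtype=int)
    n_soma = int(spec.soma_count[group])
    if soma_flat.size and n_soma > 0:
        picks = rng_th.choice(soma_flat, size=n_soma, replace=n_soma > soma_flat.size)
        centers = np.stack(np.unravel_index(picks, shape), axis=1).astype(float)
        for c in centers:
            _stamp_blob(data["th"], truth["soma"], c, spec.soma_radius_um, vs, amplitude=1.5)

    # --- capillary-like artifacts on plaque & microglia channels -----------
    scratch = np.zeros(shape, dtype=bool)
    for _ in range(spec.artifact_tube_count):
        s = rng_art.uniform(0.2, 0.8, size=3) * np.array(shape)
        d = rng_art.normal(size=3)
        d /= np.linalg.norm(d)
        L = rng_art.uniform(0.4, 0.7) * min(shape)
        p0, p1 = s - d * L / 2, s + d * L / 2
        _stamp_capsule(data["plaque"], truth["artifact"], p0, p1, 30.0, vs, amplitude=3.0)
        _stamp_capsule(data["microglia"], scratch, p0, p1, 30.0, vs, amplitude=3.0)

    # --- autofluorescence: anatomy only -------------------------------------
    grad = np.linspace(0.8, 1.2, shape[0])[:, None, None]
    data["autofluorescence"] = np.where(brain, 0.5 * grad, 0.0)

    # --- additive Gaussian noise (one stream, drawn per channel in fixed
    # order so a different channel selection cannot shift the draws) --------
    for name in CHANNELS:
        noise = rng_noise.normal(0.0, 1.0, size=shape)
        if spec.noise_sd > 0:
            data[name] = data[name] + spec.noise_sd * noise

    vs_t = tuple(float(x) for x in vs)
    out_channels = {
        name: Volume(data[name], vs_t, "atlas", subject_id, name)
        for name in channels
    }
    masks = {
        name: BinaryMask(arr.astype(np.uint8), vs_t, "atlas", subject_id, name)
        for name, arr in truth.items()
    }
    return out_channels, PhantomTruth(
        masks=masks,
        planted_effect_region_ids=planted_effect_regions(spec, atlas),
        group=group,
    )


def _truth_ball(truth, center_vox, radius_um, voxel_size_um):
    """Mark a ball (physical radius) in a boolean mask without rendering."""
    vs = np.asarray(voxel_size_um, dtype=float)
    ext = np.ceil(radius_um / vs).astype(int)
    lo = np.maximum(np.round(center_vox).astype(int) - ext, 0)
    hi = np.minimum(np.round(center_vox).astype(int) + ext + 1, truth.shape)
    if np.any(lo >= hi):
        return
    coords = [np.arange(lo[a], hi[a]) for a in range(3)]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")
    d2 = (
        ((zz - center_vox[0]) * vs[0]) ** 2
        + ((yy - center_vox[1]) * vs[1]) ** 2
        + ((xx - center_vox[2]) * vs[2]) ** 2
    )
    sl = tuple(slice(lo[a], hi[a]) for a in range(3))
    truth[sl] |= d2 <= radius_um**2


def simulate_cohort(
    spec: PhantomSpec,
    atlas: Atlas,
    channels: Sequence[str] = CHANNELS,
) -> List[Tuple[str, str, Dict[str, Volume], PhantomTruth]]:
    """Simulate a balanced two-group cohort of ``2 * n_per_group`` subjects.

    Subject seeds are spawned deterministically from ``spec.seed``.
    """
    if spec.n_per_group < 2:
        raise ValueError("n_per_group must be >= 2 (validation t-test needs >= 2 per group)")
    ss = np.random.SeedSequence(spec.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(2 * spec.n_per_group)]
    cohort = []
    i = 0
    for group in GROUPS:
        for k in range(spec.n_per_group):
            sid = f"sub-{group}{k + 1:02d}"
            chans, truth = simulate_subject(spec, atlas, group, seeds[i], sid, channels)
            cohort.append((sid, group, chans, truth))
            i += 1
    return cohort
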