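"""File plumbing: NIfTI / multi-page TIFF volumes, atlases, manifests.

NIfTI (.nii/.nii.gz) is the primary on-disk format; voxel size (µm) is
stored in the header zooms (as mm) and space/subject/channel identity in the
descrip field. Multi-page TIFF z-stacks are accepted for input with an
explicit voxel size. Atlases round-trip as a label NIfTI + hierarchy CSV
(id, name, abbrev, parent_id, depth) + exclusion-id YAML.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Union

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile
import yaml

from .atlas import Atlas, RegionNode
from .core import BinaryMask, Volume

NIFTI_EXTS = (".nii", ".nii.gz")
TIFF_EXTS = (".tif", ".tiff")


def _ext_of(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return path.suffix.lower()


def write_volume(path, v: Union[Volume, BinaryMask]) -> Path:
    """Write a Volume/BinaryMask to NIfTI (or TIFF for .tif paths)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ext = _ext_of(path)
    if ext in NIFTI_EXTS:
        vs_mm = np.asarray(v.voxel_size_um, dtype=float) / 1000.0
        affine = np.diag(list(vs_mm) + [1.0])
        img = nib.Nifti1Image(np.asarray(v.data), affine)
        img.header.set_zooms(tuple(vs_mm))
        img.header["descrip"] = f"space={v.space};sub={v.subject_id};ch={v.channel}".encode()[:79]
        img.header.set_data_dtype(v.data.dtype)
        nib.save(img, str(path))
    elif ext in TIFF_EXTS:
        tifffile.imwrite(str(path), np.asarray(v.data), photometric="minisblack")
    else:
        raise ValueError(f"unknown volume format {ext!r} for {path}")
    return path


def read_volume(
    path,
    voxel_size_um=None,
    space: Optional[str] = None,
    subject_id: str = "",
    channel: str = "",
    as_mask: bool = False,
) -> Union[Volume, BinaryMask]:
    """Read a NIfTI or multi-page TIFF volume.

    For NIfTI, voxel size and identity metadata come from the header unless
    overridden; TIFF requires an explicit ``voxel_size_um``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    ext = _ext_of(path)
    if ext in NIFTI_EXTS:
        try:
            img = nib.load(str(path))
            data = np.asanyarray(img.dataobj)
        except Exception as e:  # truncated/corrupt file
            raise ValueError(f"cannot read NIfTI file {path}: {e}") from e
        if voxel_size_um is None:
            voxel_size_um = tuple(float(z) * 1000.0 for z in img.header.get_zooms()[:3])
        descrip = bytes(img.header["descrip"].tobytes()).split(b"\x00")[0].decode(errors="ignore")
        meta = dict(kv.split("=", 1) for kv in descrip.split(";") if "=" in kv)
        space = space or meta.get("space", "tissue")
        subject_id = subject_id or meta.get("sub", "")
        channel = channel or meta.get("ch", "")
    elif ext in TIFF_EXTS:
        try:
            data = tifffile.imread(str(path))
        except Exception as e:
            raise ValueError(f"cannot read TIFF file {path}: {e}") from e
        if voxel_size_um is None:
            raise ValueError(f"TIFF input {path} requires an explicit voxel_size_um")
        space = space or "tissue"
    else:
        raise ValueError(f"unknown volume format {ext!r} for {path}")
    cls = BinaryMask if as_mask else Volume
    return cls(data, voxel_size_um, space, subject_id, channel)


# ---------------------------------------------------------------------------
# atlas
# ---------------------------------------------------------------------------

def write_atlas(directory, atlas: Atlas, stem: str = "atlas") -> dict:
    """Write labels (.nii.gz), hierarchy CSV and exclusion YAML; returns paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    labels_path = directory / f"{stem}_labels.nii.gz"
    vol = Volume(atlas.labels, atlas.voxel_size_um, "atlas", channel="labels")
    write_volume(labels_path, vol)
    hier_path = directory / f"{stem}_hierarchy.csv"
    pd.DataFrame(
        [
            dict(id=n.id, name=n.name, abbrev=n.abbrev,
                 parent_id=-1 if n.parent_id is None else n.parent_id, depth=n.depth)
            for n in atlas.hierarchy
        ]
    ).to_csv(hier_path, index=False)
    excl_path = directory / f"{stem}_exclusions.yaml"
    with open(excl_path, "w") as fh:
        yaml.safe_dump({"exclusion_ids": sorted(atlas.exclusion_ids)}, fh)
    return {"labels": labels_path, "hierarchy": hier_path, "exclusions": excl_path}


def read_atlas(labels_path, hierarchy_path, exclusions_path=None) -> Atlas:
    vol = read_volume(labels_path, space="atlas")
    df = pd.read_csv(hierarchy_path)
    nodes = [
        RegionNode(
            int(r.id), str(r.name), str(r.abbrev),
            None if int(r.parent_id) < 0 else int(r.parent_id), int(r.depth),
        )
        for r in df.itertuples()
    ]
    excl = set()
    if exclusions_path is not None and Path(exclusions_path).exists():
        with open(exclusions_path) as fh:
            excl = set(yaml.safe_load(fh).get("exclusion_ids", []))
    labels = np.asarray(vol.data)
    if not np.issubdtype(labels.dtype, np.integer):
        labels = labels.astype(np.int32)
    return Atlas(labels, vol.voxel_size_um, nodes, excl)


# ---------------------------------------------------------------------------
# manifests & checksums
# ---------------------------------------------------------------------------

def write_cohort_manifest(path, rows: pd.DataFrame) -> Path:
    """Cohort manifest CSV: subject_id, group, one column per channel path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows.to_csv(path, index=False)
    return path


def read_manifest(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    df = pd.read_csv(path)
    for col in ("subject_id", "group"):
        if col not in df.columns:
            raise ValueError(f"manifest {path} lacks required column {col!r}")
    return df


def array_checksum(arr: np.ndarray) -> str:
    """SHA-256 of an array's bytes (shape- and dtype-tagged)."""
    h = hashlib.sha256()
    arr = np.ascontiguousarray(arr)
    h.update(str(arr.shape).encode())
    h.update(str(arr.dtype).encode())
    h.update(arr.tobytes())
    return h.hexdigest()


def write_json(path, obj) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
    return path
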