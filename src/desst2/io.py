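"""NIfTI and CSV plumbing.

Volumes (echoes, label maps, T2 maps) travel as NIfTI with the voxel
spacing encoded in the affine; tables travel as CSV.  Nothing here does
science — it only keeps geometry and invalid markers intact across disk.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import nibabel as nib
import numpy as np

from .t2_mapping import T2Map, TissueLabelMap, VolumeGrid

__all__ = [
    "write_volume",
    "read_volume",
    "write_labels",
    "read_labels",
    "write_t2_map",
    "read_t2_map",
    "file_sha256",
]


def write_volume(vol: VolumeGrid, path) -> None:
    img = nib.Nifti1Image(vol.values.astype(np.float32), vol.affine)
    img.header.set_zooms(vol.spacing_mm)
    nib.save(img, str(path))


def read_volume(path) -> VolumeGrid:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeGrid(np.asarray(img.dataobj, dtype=float), spacing, img.affine)


def write_labels(labels: TissueLabelMap, path, meta_path=None) -> None:
    """Label volume as integer NIfTI plus a small CSV of label semantics."""
    affine = np.diag([0.3, 0.3, 1.6, 1.0])
    img = nib.Nifti1Image(labels.labels.astype(np.int16), affine)
    nib.save(img, str(path))
    if meta_path is not None:
        with open(meta_path, "w") as fh:
            fh.write("label,tissue_class,t1_ms\n")
            for lab in labels.present_labels():
                fh.write(f"{lab},{labels.tissue_class[lab]},{labels.t1_ms[lab]}\n")


def read_labels(path, meta_path) -> TissueLabelMap:
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj).astype(np.int16)
    classes: dict[int, str] = {}
    t1: dict[int, float] = {}
    lines = Path(meta_path).read_text().strip().splitlines()[1:]
    for line in lines:
        lab, cls, t1_ms = line.split(",")
        classes[int(lab)] = cls
        t1[int(lab)] = float(t1_ms)
    return TissueLabelMap(arr, classes, t1)


def write_t2_map(t2map: T2Map, path, flags_path=None) -> None:
    """T2 values as float NIfTI (NaN = invalid); flags optionally alongside."""
    affine = np.diag(list(t2map.spacing_mm) + [1.0])
    nib.save(nib.Nifti1Image(t2map.values.astype(np.float32), affine), str(path))
    if flags_path is not None:
        nib.save(nib.Nifti1Image(t2map.flags.astype(np.int8), affine), str(flags_path))


def read_t2_map(path, flags_path=None) -> T2Map:
    img = nib.load(str(path))
    values = np.asarray(img.dataobj, dtype=float)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if flags_path is not None:
        flags = np.asarray(nib.load(str(flags_path)).dataobj).astype(np.int8)
    else:
        flags = np.where(np.isfinite(values), 0, -1).astype(np.int8)
    return T2Map(values, flags, spacing)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
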