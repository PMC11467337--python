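"""Tomogram and table I/O.

HDF5 is the canonical container: one dataset ``ri`` with attributes
``voxel_spacing`` (dz, dy, dx in um) and ``medium_ri``; ground-truth label
maps travel as a parallel ``labels`` dataset.  Multi-page 32-bit TIFF export
is supported with a JSON metadata sidecar (TIFF carries no RI metadata of its
own; a missing sidecar is an error, never a silent default).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .core import Tomogram
from .morphometry import SegmentationMask

__all__ = ["MetadataError", "write_tomogram", "read_tomogram",
           "write_tomogram_tiff", "read_tomogram_tiff", "read_labels"]


class MetadataError(KeyError):
    """A required attribute is missing from a tomogram container."""


def write_tomogram(tomo: Tomogram, path, labels: np.ndarray | None = None) -> Path:
    """Write a tomogram (and optional label map) to HDF5."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        d = f.create_dataset("ri", data=np.asarray(tomo.ri, dtype=np.float32),
                             compression="gzip", compression_opts=1)
        d.attrs["voxel_spacing"] = np.asarray(tomo.voxel_spacing, dtype=np.float64)
        d.attrs["medium_ri"] = float(tomo.medium_ri)
        if tomo.image_id is not None:
            d.attrs["image_id"] = tomo.image_id
        if labels is not None:
            f.create_dataset("labels", data=np.asarray(labels, dtype=np.uint8),
                             compression="gzip", compression_opts=1)
    return path


def read_tomogram(path) -> Tomogram:
    """Read a tomogram from HDF5; raises :class:`MetadataError` on missing attrs."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        if "ri" not in f:
            raise MetadataError(f"{path}: missing dataset 'ri'")
        d = f["ri"]
        for attr in ("voxel_spacing", "medium_ri"):
            if attr not in d.attrs:
                raise MetadataError(f"{path}: missing attribute {attr!r} on dataset 'ri'")
        return Tomogram(
            ri=d[()].astype(np.float64),
            voxel_spacing=tuple(float(s) for s in d.attrs["voxel_spacing"]),
            medium_ri=float(d.attrs["medium_ri"]),
            image_id=str(d.attrs["image_id"]) if "image_id" in d.attrs else None,
        )


def read_labels(path, provenance: str = "ground_truth") -> SegmentationMask:
    path = Path(path)
    with h5py.File(path, "r") as f:
        if "labels" not in f:
            raise MetadataError(f"{path}: missing dataset 'labels'")
        return SegmentationMask(f["labels"][()], provenance=provenance)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_tomogram_tiff(tomo: Tomogram, path) -> Path:
    """Write a multi-page float32 TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(tomo.ri, dtype=np.float32),
                     photometric="minisblack")
    meta = {"voxel_spacing": list(tomo.voxel_spacing), "medium_ri": tomo.medium_ri,
            "image_id": tomo.image_id}
    _sidecar(path).write_text(json.dumps(meta))
    return path


def read_tomogram_tiff(path) -> Tomogram:
    path = Path(path)
    side = _sidecar(path)
    if not side.exists():
        raise MetadataError(f"{path}: missing metadata sidecar {side.name}")
    meta = json.loads(side.read_text())
    for key in ("voxel_spacing", "medium_ri"):
        if key not in meta:
            raise MetadataError(f"{side}: missing key {key!r}")
    return Tomogram(
        ri=tifffile.imread(path).astype(np.float64),
        voxel_spacing=tuple(meta["voxel_spacing"]),
        medium_ri=float(meta["medium_ri"]),
        image_id=meta.get("image_id"),
    )
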