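"""NIfTI and JSON serialization for masks, label volumes and fluence maps.

Volumes are written as NIfTI (.nii / .nii.gz) with an isotropic affine
carrying the voxel pitch in mm. Label volumes use the integer convention
INTERIOR=0, WALL=1, TISSUE=2, BOUNDARY=3 (see :class:`pdtplan.geometry.Region`).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .geometry import LabelVolume

__all__ = [
    "save_volume_nifti",
    "load_mask_nifti",
    "save_label_volume",
    "load_label_volume",
    "write_manifest",
]


def _affine(pitch_mm: float) -> np.ndarray:
    aff = np.diag([pitch_mm, pitch_mm, pitch_mm, 1.0])
    return aff


def save_volume_nifti(array: np.ndarray, pitch_mm: float, path: str | Path) -> None:
    """Write a 3D array (mask, labels or fluence) with pitch in the header."""
    img = nib.Nifti1Image(np.asarray(array), _affine(pitch_mm))
    nib.save(img, str(path))


def load_mask_nifti(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a binary cavity mask; returns (bool mask, pitch_mm)."""
    img = nib.load(str(path))
    pitch = float(img.header.get_zooms()[0])
    return np.asarray(img.dataobj) > 0, pitch


def save_label_volume(lv: LabelVolume, path: str | Path) -> None:
    save_volume_nifti(lv.labels.astype(np.uint8), lv.pitch_mm, path)


def load_label_volume(path: str | Path) -> LabelVolume:
    img = nib.load(str(path))
    pitch = float(img.header.get_zooms()[0])
    labels = np.asarray(img.dataobj).astype(np.uint8)
    lv = LabelVolume(labels, pitch)
    lv.validate()
    return lv


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_manifest(manifest: dict, path: str | Path) -> None:
    """Write a provenance manifest (seeds, packet counts, optics table) as JSON."""
    Path(path).write_text(json.dumps(_jsonable(manifest), indent=2, allow_nan=True))
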