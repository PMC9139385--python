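"""Readers, writers, resampling and run metadata.

Volumes travel as NIfTI (float32 HU for CT, uint8 for masks) with the
spacing encoded in a diagonal affine; DICOM series are read with pydicom
(slices sorted by position, rescale slope/intercept applied to give HU).
Every artifact written by the command-line tools gets a JSON sidecar
with the seed and a digest of the configuration that produced it.

Coordinate convention: axes (x: left->right, y: posterior->anterior,
z: inferior->superior), voxel indices 0-based, physical position =
index * spacing (corner-anchored).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .phantom import CTVolume, SegmentationVolume

__all__ = [
    "load_ct", "save_ct", "load_mask", "save_mask", "resample_volume",
    "write_sidecar",
]


def _affine(spacing_mm):
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    return aff


def save_ct(ct: CTVolume, path) -> None:
    img = nib.Nifti1Image(ct.voxels.astype(np.float32),
                          _affine(ct.spacing_mm))
    nib.save(img, str(path))


def save_mask(seg: SegmentationVolume, path) -> None:
    img = nib.Nifti1Image(seg.mask.astype(np.uint8), _affine(seg.spacing_mm))
    nib.save(img, str(path))


def _load_nifti(path):
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def _load_dicom_series(directory: Path) -> CTVolume:
    import pydicom

    files = sorted(directory.glob("*.dcm")) or sorted(
        p for p in directory.iterdir() if p.is_file())
    if not files:
        raise FileNotFoundError(f"no DICOM files in {directory}")
    slices = [pydicom.dcmread(str(f)) for f in files]
    for ds in slices:
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise ValueError(f"missing rescale tags in {ds.filename}")
    orientations = {tuple(np.round(ds.ImageOrientationPatient, 4))
                    for ds in slices if "ImageOrientationPatient" in ds}
    if len(orientations) > 1:
        raise ValueError("mixed-orientation DICOM series")
    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    slope = float(slices[0].RescaleSlope)
    intercept = float(slices[0].RescaleIntercept)
    stack = np.stack([ds.pixel_array.astype(np.float32) for ds in slices])
    hu = stack * slope + intercept
    # pixel_array is (row, col) = (y, x); stack axis is z
    voxels = np.transpose(hu, (2, 1, 0))
    px_y, px_x = (float(v) for v in slices[0].PixelSpacing)
    if len(slices) > 1:
        dz = float(slices[1].ImagePositionPatient[2]) - \
            float(slices[0].ImagePositionPatient[2])
    else:
        dz = float(getattr(slices[0], "SliceThickness", 1.0))
    return CTVolume(voxels, (px_x, px_y, abs(dz)),
                    rescale_slope=slope, rescale_intercept=intercept)


def load_ct(path) -> CTVolume:
    """Load a CT volume in HU from a NIfTI file or a DICOM series dir."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(str(p))
    if p.is_dir():
        return _load_dicom_series(p)
    data, spacing = _load_nifti(p)
    return CTVolume(np.asarray(data, dtype=np.float32), spacing)


def load_mask(path) -> SegmentationVolume:
    data, spacing = _load_nifti(Path(path))
    return SegmentationVolume(np.asarray(data) > 0, spacing)


def resample_volume(vol: CTVolume, new_spacing_mm) -> CTVolume:
    """Trilinear resampling onto a grid with the requested spacing.

    The physical extent is preserved to within one output voxel per axis.
    """
    new_spacing = tuple(float(s) for s in new_spacing_mm)
    if any(s <= 0 for s in new_spacing):
        raise ValueError("spacing must be > 0")
    if new_spacing == tuple(vol.spacing_mm):
        return CTVolume(vol.voxels.copy(), vol.spacing_mm,
                        vol.rescale_slope, vol.rescale_intercept)
    factors = [o / n for o, n in zip(vol.spacing_mm, new_spacing)]
    new_shape = [max(1, int(round(s * f)))
                 for s, f in zip(vol.voxels.shape, factors)]
    if min(new_shape) < 1:
        raise ValueError("degenerate output grid")
    # map output voxel centres to input index space (corner-anchored)
    coords = np.meshgrid(*[(np.arange(ns) + 0.5) * new_spacing[i]
                           / vol.spacing_mm[i] - 0.5
                           for i, ns in enumerate(new_shape)], indexing="ij")
    out = ndimage.map_coordinates(vol.voxels.astype(np.float64),
                                  np.stack(coords), order=1, mode="nearest")
    return CTVolume(out.astype(np.float32), new_spacing,
                    vol.rescale_slope, vol.rescale_intercept)


def config_digest(obj) -> str:
    """Short stable digest of a (nested) configuration mapping."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_sidecar(artifact_path, config: dict, seed: int) -> None:
    """JSON sidecar recording how an artifact can be regenerated."""
    side = Path(str(artifact_path) + ".json")
    payload = {"seed": int(seed), "config": config,
               "config_digest": config_digest(config)}
    side.write_text(json.dumps(payload, indent=2, default=str))
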