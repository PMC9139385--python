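"""Simulated bi-planar radiographs (DRRs) from a signal volume.

The default projector is parallel-beam: a pixel is the line integral of
the signal along the projection axis (AP projects along y, Lat along x),
mapped to radiographic intensity by ``1 - exp(-k * integral)``.  Parallel
geometry keeps exact conservation laws (detector sum = volume sum times
the axis spacing) that anchor the test suite.  A simple cone-beam mode
(point source, ray-driven trilinear sampling) is available for geometry
experiments but is not used by the training pipeline.

Detector convention: image row 0 is superior; AP columns run left->right
in the patient frame, Lat columns posterior->anterior.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .enhance import EnhancedVolume

__all__ = [
    "ProjectionGeometry", "DRRPair", "line_integral", "to_radiograph",
    "cone_line_integral", "make_biplanar", "spine_crop_roi",
]

#: Intensity the median positive ray maps to when the attenuation scale is
#: chosen automatically.
_AUTO_TARGET = 0.7

_VIEW_AXIS = {"AP": 1, "Lat": 0}    # projection axis in (x, y, z) order


@dataclass(frozen=True)
class ProjectionGeometry:
    """Geometry of one simulated radiograph."""

    view: str                              # "AP" or "Lat"
    mode: str = "parallel"                 # "parallel" or "cone"
    attenuation_scale: Optional[float] = None   # per-mm; None -> auto
    detector_shape: tuple = (128, 256)     # (width, height) pixels
    source_distance_mm: float = 1000.0     # cone mode only

    def __post_init__(self):
        if self.view not in _VIEW_AXIS:
            raise ValueError(f"unknown view {self.view!r}")
        if self.mode not in ("parallel", "cone"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.attenuation_scale is not None and self.attenuation_scale <= 0:
            raise ValueError("attenuation_scale must be > 0")
        w, h = self.detector_shape
        if w <= 0 or h <= 0:
            raise ValueError("detector_shape must be positive")


@dataclass
class DRRPair:
    """AP and Lat radiographs of one case, each in [0, 1]."""

    ap: np.ndarray
    lat: np.ndarray
    geometry: tuple
    source_id: str = ""

    def __post_init__(self):
        self.ap = np.asarray(self.ap, dtype=np.float32)
        self.lat = np.asarray(self.lat, dtype=np.float32)
        if self.ap.shape != self.lat.shape:
            raise ValueError("AP and Lat images must share detector shape")
        for img in (self.ap, self.lat):
            if img.min() < 0 or img.max() > 1:
                raise ValueError("radiograph values must lie in [0, 1]")


def line_integral(volume: EnhancedVolume, view: str) -> np.ndarray:
    """Parallel-beam line integral along the view axis.

    Returns an image of shape (rows=z, cols=x or y) with row 0 superior.
    """
    if view not in _VIEW_AXIS:
        raise ValueError(f"unknown view {view!r}")
    axis = _VIEW_AXIS[view]
    integ = volume.signal.sum(axis=axis, dtype=np.float64) \
        * volume.spacing_mm[axis]
    # remaining axes: AP -> (x, z), Lat -> (y, z); to (z, cols), z flipped
    return integ.T[::-1].copy()


def to_radiograph(integrals: np.ndarray, k: float) -> np.ndarray:
    """Map non-negative line integrals to intensities 1 - exp(-k*I)."""
    if k <= 0:
        raise ValueError("attenuation scale k must be > 0")
    integrals = np.asarray(integrals)
    if integrals.min() < 0:
        raise ValueError("line integrals must be non-negative")
    return -np.expm1(-k * integrals)


def _auto_scale(integrals: np.ndarray) -> float:
    pos = integrals[integrals > 0]
    if pos.size == 0:
        return 1.0
    return float(-np.log1p(-_AUTO_TARGET) / np.median(pos))


def cone_line_integral(volume: EnhancedVolume, view: str,
                       source_distance_mm: float,
                       n_samples: int = 96) -> np.ndarray:
    """Point-source divergent-ray projection by trilinear ray sampling.

    The source sits on the negative side of the projection axis at
    ``source_distance_mm`` from the volume centre; the detector plane
    coincides with the far face of the volume, one pixel per boundary
    voxel (then resampled downstream like the parallel case).
    """
    if view not in _VIEW_AXIS:
        raise ValueError(f"unknown view {view!r}")
    axis = _VIEW_AXIS[view]
    shape = volume.signal.shape
    sp = volume.spacing_mm
    extent = [shape[i] * sp[i] for i in range(3)]
    centre = [e / 2.0 for e in extent]
    u_axis, w_axis = [i for i in range(3) if i != axis][0], 2

    src = list(centre)
    src[axis] = centre[axis] - source_distance_mm
    det_u = (np.arange(shape[u_axis]) + 0.5) * sp[u_axis]
    det_w = (np.arange(shape[w_axis]) + 0.5) * sp[w_axis]
    U, W = np.meshgrid(det_u, det_w, indexing="ij")
    det = np.zeros(U.shape + (3,))
    det[..., axis] = extent[axis]
    det[..., u_axis] = U
    det[..., w_axis] = W

    src_arr = np.asarray(src)
    ray = det - src_arr                                    # (u, w, 3)
    # sample only the axial slab containing the volume
    t0 = (0.0 - src_arr[axis]) / ray[..., axis].mean()
    t = np.linspace(t0, 1.0, n_samples)
    pts = src_arr + t[:, None, None, None] * ray           # (s, u, w, 3)
    idx = [(pts[..., i] / sp[i]) - 0.5 for i in range(3)]
    samples = ndimage.map_coordinates(volume.signal, np.stack(idx),
                                      order=1, mode="constant", cval=0.0)
    seg = np.linalg.norm(ray, axis=-1) * (1.0 - t0) / (n_samples - 1)
    integ = samples.sum(axis=0) * seg                      # (u, w)
    return integ.T[::-1].copy()


def spine_crop_roi(mask: np.ndarray, margin: int = 8) -> tuple:
    """Mask-tight bounding box dilated by ``margin`` voxels, clipped to grid."""
    nz = np.nonzero(mask)
    if len(nz[0]) == 0:
        raise ValueError("empty mask: cannot derive a crop ROI")
    lo = [max(int(a.min()) - margin, 0) for a in nz]
    hi = [min(int(a.max()) + 1 + margin, s) for a, s in zip(nz, mask.shape)]
    return tuple((l, h) for l, h in zip(lo, hi))


def _resize_bilinear(img: np.ndarray, out_shape: tuple) -> np.ndarray:
    from skimage.transform import resize
    return resize(img, out_shape, order=1, mode="edge",
                  anti_aliasing=False, preserve_range=True)


def make_biplanar(volume: EnhancedVolume,
                  geometry: tuple[ProjectionGeometry, ProjectionGeometry]
                  = (ProjectionGeometry("AP"), ProjectionGeometry("Lat")),
                  crop: Optional[tuple] = None,
                  source_id: str = "") -> DRRPair:
    """Project a signal volume into an AP/Lat radiograph pair.

    ``crop`` is ((x_lo, x_hi), (y_lo, y_hi), (z_lo, z_hi)) in voxel
    indices; by default the bounding box of the nonzero signal dilated by
    8 voxels.  Each view is cropped to the ROI axes it sees and resampled
    bilinearly to the detector shape.
    """
    if crop is None:
        crop = spine_crop_roi(volume.signal > 0, margin=8)
    if any(hi <= lo for lo, hi in crop):
        raise ValueError("empty crop ROI")

    images = {}
    for geom in geometry:
        if geom.mode == "cone":
            integ = cone_line_integral(volume, geom.view,
                                       geom.source_distance_mm)
        else:
            integ = line_integral(volume, geom.view)
        axis = _VIEW_AXIS[geom.view]
        col_axis = 1 if axis == 0 else 0           # volume axis on columns
        nz = volume.signal.shape[2]
        zlo, zhi = crop[2]
        clo, chi = crop[col_axis]
        # rows are flipped z: volume z index z maps to row nz-1-z
        sub = integ[nz - zhi:nz - zlo, clo:chi]
        k = geom.attenuation_scale
        if k is None:
            k = _auto_scale(sub)
        w, h = geom.detector_shape
        images[geom.view] = _resize_bilinear(to_radiograph(sub, k), (h, w))
    return DRRPair(np.clip(images["AP"], 0.0, 1.0),
                   np.clip(images["Lat"], 0.0, 1.0),
                   tuple(geometry), source_id)
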