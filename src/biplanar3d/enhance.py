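"""Empirical bone-signal enhancement of CT volumes.

Raw Hounsfield values are converted to detector-style "imaging signal"
values by a fixed empirical recipe: threshold filtering, a body mask,
inversion of the DICOM rescale transform, a signal window, and a x3
amplification of the strongest bone signal.  The un-enhanced control
condition ("original") is the bare rescale inversion with no filtering.

Scalar rules (applied elementwise):

* ``filter_hu``      — clamp below -1024 HU; values above 1000 HU are set
  to 0 HU (a deliberate, literal quirk of the recipe: the densest bone is
  knocked down to water level rather than clipped).
* ``body_mask``      — 1 where HU > -400, else 0.
* ``hu_to_signal``   — signal = (HU - intercept) / slope, the exact inverse
  of the DICOM rescale transform.
* ``window_amplify`` — zero outside the open window (874, 2024); tripled
  above 1300.

``enhance_volume`` composes them per voxel and multiplies the body mask
into the *windowed signal*, so every out-of-body voxel (air, lung) ends at
exactly zero signal and the background of downstream radiographs is dark.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .phantom import CTVolume

__all__ = [
    "Provenance",
    "EnhancedVolume",
    "filter_hu",
    "body_mask",
    "hu_to_signal",
    "window_amplify",
    "enhance_volume",
    "original_signal_volume",
]


class Provenance(str, Enum):
    ORIGINAL = "original"
    ENHANCED = "enhanced"


@dataclass
class EnhancedVolume:
    """A non-negative imaging-signal volume derived from a CT volume."""

    signal: np.ndarray
    spacing_mm: tuple
    provenance: Provenance

    def __post_init__(self) -> None:
        # keep the incoming float dtype: projections accumulate in float64
        # and must conserve mass to tight relative tolerance
        self.signal = np.asarray(self.signal)
        if not np.issubdtype(self.signal.dtype, np.floating):
            self.signal = self.signal.astype(np.float64)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.provenance = Provenance(self.provenance)


def _as_finite_array(v):
    arr = np.asarray(v, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError("input HU values must be finite")
    return arr


def filter_hu(v):
    """Low/high HU threshold filter: <-1024 -> -1024; >1000 -> 0."""
    arr = _as_finite_array(v)
    out = np.where(arr < -1024.0, -1024.0, arr)
    out = np.where(arr > 1000.0, 0.0, out)
    return out if out.ndim else float(out)


def body_mask(v):
    """Empirical body mask: 1 where HU > -400 (strictly), else 0."""
    arr = _as_finite_array(v)
    out = (arr > -400.0).astype(np.float64)
    return out if out.ndim else float(out)


def hu_to_signal(v, slope: float, intercept: float):
    """Invert the DICOM rescale transform: signal = (HU - intercept)/slope."""
    if slope == 0:
        raise ValueError("rescale slope must be nonzero")
    arr = np.asarray(v, dtype=np.float64)
    out = (arr - intercept) / slope
    return out if out.ndim else float(out)


def window_amplify(s):
    """Signal window (874, 2024), open at both ends; values > 1300 tripled."""
    arr = np.asarray(s, dtype=np.float64)
    out = np.where((arr <= 874.0) | (arr >= 2024.0), 0.0, arr)
    out = np.where((arr > 1300.0) & (arr < 2024.0), 3.0 * arr, out)
    return out if out.ndim else float(out)


def enhance_volume(ct: CTVolume) -> EnhancedVolume:
    """Apply the full bone-enhancement recipe to a CT volume.

    Per voxel: window_amplify(hu_to_signal(filter_hu(v))) * body_mask(v).
    The mask multiplies the windowed signal (not the filtered HU) so that
    masked-out voxels are exactly zero rather than landing at the water-
    equivalent stored value -intercept/slope inside the window.
    """
    v = ct.voxels
    sig = window_amplify(hu_to_signal(filter_hu(v), ct.rescale_slope,
                                      ct.rescale_intercept))
    sig = sig * body_mask(v)
    return EnhancedVolume(sig, ct.spacing_mm, Provenance.ENHANCED)


def original_signal_volume(ct: CTVolume) -> EnhancedVolume:
    """Un-enhanced control: bare rescale inversion of HU clamped at -1024."""
    if ct.rescale_slope == 0:
        raise ValueError("rescale slope must be nonzero")
    v = np.maximum(np.asarray(ct.voxels, dtype=np.float64), -1024.0)
    sig = (v - ct.rescale_intercept) / ct.rescale_slope
    return EnhancedVolume(sig, ct.spacing_mm, Provenance.ORIGINAL)
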