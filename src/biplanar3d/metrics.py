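"""Volumetric overlap and projection-similarity metrics.

Five per-case scores compare a predicted binary spine volume A against
its ground truth B:

* ``dsc``  Dice similarity coefficient, 2|A∩B| / (|A|+|B|)
* ``jsc``  Jaccard similarity coefficient, |A∩B| / |A∪B|
* ``ov``   overlap volume, |A∩B| / min(|A|,|B|)
* ``ssim_ap`` / ``ssim_lat``  structural similarity between the AP/Lat
  sum-projections of the two volumes.

SSIM uses the standard luminance-contrast-structure product with
stabilizers C1=(0.01 L)^2, C2=(0.03 L)^2, C3=C2/2 (L=1 for normalized
images) and an 11x11 Gaussian window, sigma 1.5; means and (co)variances
are Gaussian-filtered moments and the half-window border is excluded
from the average, matching the canonical reference implementation.  A
uniform window is available via ``gaussian=False``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import SegmentationVolume

__all__ = [
    "MetricReport", "dsc", "jsc", "ov", "ssim", "projection_for_ssim",
    "evaluate_case",
]

_VIEW_AXIS = {"AP": 1, "Lat": 0}


@dataclass
class MetricReport:
    """Per-case evaluation scores."""

    dsc: float
    jsc: float
    ov: float
    ssim_ap: float
    ssim_lat: float
    case_id: str = ""


def _binary_pair(a, b):
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("volumes must share a shape")
    return a.astype(bool), b.astype(bool)


def dsc(a, b) -> float:
    """Dice coefficient; two empty volumes count as perfect agreement."""
    a, b = _binary_pair(a, b)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        warnings.warn("both volumes empty: DSC defined as 1", stacklevel=2)
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def jsc(a, b) -> float:
    """Jaccard coefficient; two empty volumes count as perfect agreement."""
    a, b = _binary_pair(a, b)
    union = int((a | b).sum())
    if union == 0:
        warnings.warn("both volumes empty: JSC defined as 1", stacklevel=2)
        return 1.0
    return int((a & b).sum()) / union


def ov(a, b) -> float:
    """Overlap volume |A∩B| / min(|A|,|B|); both volumes must be nonempty."""
    a, b = _binary_pair(a, b)
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 or nb == 0:
        raise ValueError("overlap volume undefined for an empty volume")
    return int((a & b).sum()) / min(na, nb)


def ssim(x, y, window: int = 11, gaussian: bool = True,
         sigma: float = 1.5) -> float:
    """Mean structural similarity of two images with values in [0, 1]."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 2:
        raise ValueError("inputs must be 2D images of identical shape")
    if min(x.shape) < window:
        raise ValueError(f"image smaller than the {window}x{window} window")

    if gaussian:
        truncate = (window - 1) / 2 / sigma     # radius exactly (window-1)/2
        def filt(img):
            return ndimage.gaussian_filter(img, sigma, truncate=truncate,
                                           mode="reflect")
    else:
        def filt(img):
            return ndimage.uniform_filter(img, window, mode="reflect")

    c1 = 0.01 ** 2
    c2 = 0.03 ** 2
    mx, my = filt(x), filt(y)
    mxx, myy, mxy = filt(x * x), filt(y * y), filt(x * y)
    vx = mxx - mx * mx
    vy = myy - my * my
    cxy = mxy - mx * my
    s = ((2 * mx * my + c1) * (2 * cxy + c2)) / \
        ((mx * mx + my * my + c1) * (vx + vy + c2))
    pad = (window - 1) // 2
    return float(s[pad:s.shape[0] - pad, pad:s.shape[1] - pad].mean())


def projection_for_ssim(volume, view: str) -> np.ndarray:
    """Sum-projection of a binary volume, min-max normalized to [0, 1].

    Orientation follows the radiograph convention (row 0 superior); an
    all-constant projection normalizes to zeros.
    """
    if view not in _VIEW_AXIS:
        raise ValueError(f"unknown view {view!r}")
    vol = np.asarray(volume)
    proj = vol.sum(axis=_VIEW_AXIS[view], dtype=np.float64).T[::-1]
    lo, hi = proj.min(), proj.max()
    if hi == lo:
        return np.zeros_like(proj)
    return (proj - lo) / (hi - lo)


def evaluate_case(pred: SegmentationVolume, gt: SegmentationVolume,
                  case_id: str = "") -> MetricReport:
    """All five metrics for one predicted/ground-truth volume pair."""
    a, b = pred.mask, gt.mask
    if a.shape != b.shape:
        raise ValueError("prediction and ground truth must share a grid")
    return MetricReport(
        dsc=dsc(a, b),
        jsc=jsc(a, b),
        ov=ov(a, b),
        ssim_ap=ssim(projection_for_ssim(a, "AP"),
                     projection_for_ssim(b, "AP")),
        ssim_lat=ssim(projection_for_ssim(a, "Lat"),
                      projection_for_ssim(b, "Lat")),
        case_id=case_id,
    )
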