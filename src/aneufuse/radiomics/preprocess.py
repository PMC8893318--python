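"""Radiomics preprocessing: isotropic resampling, intensity rescaling and
gray-level discretization.

The battery runs on images resampled to 0.5 x 0.5 x 0.5 mm^3 (trilinear for
the image, nearest-neighbour for the binary mask, which conserves mask
volume) and min–max rescaled over the whole image to the range [0, 100].
Discretization is fixed-bin-count over the in-mask intensity range
(default 32 bins).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk

from ..types import SegMask, ValidationError, VolumeImage

log = logging.getLogger(__name__)

TARGET_SPACING = 0.5  # mm, isotropic
INTENSITY_RANGE = (0.0, 100.0)
DEFAULT_BINS = 32


@dataclass
class DiscretizedROI:
    """Gray-level map of the region of interest.

    ``levels`` holds integers 1..n_levels inside the mask and 0 outside;
    ``n_levels`` is 1 only for a constant ROI.
    """

    levels: np.ndarray
    n_levels: int
    mask: np.ndarray  # bool
    spacing: np.ndarray

    def __post_init__(self) -> None:
        inside = self.levels[self.mask]
        if inside.size == 0:
            raise ValidationError("empty ROI")
        if inside.min() < 1 or inside.max() > self.n_levels:
            raise ValidationError("in-mask level outside [1, n_levels]")


def _to_sitk(data: np.ndarray, spacing, origin) -> sitk.Image:
    img = sitk.GetImageFromArray(np.asarray(data, dtype=float).transpose(2, 1, 0))
    img.SetSpacing(tuple(np.asarray(spacing, dtype=float)))
    img.SetOrigin(tuple(np.asarray(origin, dtype=float)))
    return img


def _resample(img: sitk.Image, size, spacing, nearest: bool = False) -> sitk.Image:
    res = sitk.ResampleImageFilter()
    res.SetOutputSpacing([spacing] * 3)
    res.SetSize([int(s) for s in size])
    res.SetOutputOrigin(img.GetOrigin())
    res.SetOutputDirection(img.GetDirection())
    res.SetInterpolator(sitk.sitkNearestNeighbor if nearest else sitk.sitkLinear)
    res.SetDefaultPixelValue(0.0)
    return res.Execute(img)


def preprocess(volume: VolumeImage, mask: SegMask) -> tuple[VolumeImage, SegMask]:
    """Resample an aligned volume/mask pair to 0.5 mm isotropic and rescale
    intensities to [0, 100].

    The resampling grid is anchored at the original origin with
    ``ceil(extent / 0.5)`` voxels per axis.  A constant image maps to all
    zeros (degenerate min = max, logged).  Raises :class:`ValidationError`
    if the mask is empty after resampling.
    """
    mask.check_aligned(volume)
    extent = np.array(volume.shape) * volume.spacing
    size = np.ceil(extent / TARGET_SPACING).astype(int)

    if np.allclose(volume.spacing, TARGET_SPACING):
        data = volume.data.copy()
        mdata = mask.data.copy()
    else:
        vimg = _resample(_to_sitk(volume.data, volume.spacing, volume.origin), size, TARGET_SPACING)
        mimg = _resample(
            _to_sitk(mask.data.astype(float), mask.spacing, mask.origin),
            size, TARGET_SPACING, nearest=True,
        )
        data = sitk.GetArrayFromImage(vimg).transpose(2, 1, 0)
        mdata = sitk.GetArrayFromImage(mimg).transpose(2, 1, 0) >= 0.5

    lo, hi = float(data.min()), float(data.max())
    if hi - lo <= 0:
        log.warning("constant image: min-max rescale degenerate, mapping to 0")
        data = np.zeros_like(data)
    else:
        a, b = INTENSITY_RANGE
        data = (data - lo) / (hi - lo) * (b - a) + a

    out_spacing = [TARGET_SPACING] * 3
    new_mask = SegMask(data=np.asarray(mdata, dtype=np.uint8), spacing=out_spacing, origin=volume.origin)
    if new_mask.n_foreground == 0:
        raise ValidationError("mask empty after resampling")
    return (
        VolumeImage(data=data, spacing=out_spacing, origin=volume.origin),
        new_mask,
    )


def discretize(volume: VolumeImage, mask: SegMask, n_bins: int = DEFAULT_BINS) -> DiscretizedROI:
    """Fixed-bin-count discretization over the in-mask intensity range.

    ``level = min(floor((x - min)/w) + 1, n_bins)`` with bin width
    ``w = (max - min)/n_bins``.  A constant ROI yields a single level.
    """
    if n_bins < 2:
        raise ValidationError(f"n_bins must be >= 2, got {n_bins}")
    mask.check_aligned(volume)
    m = mask.data
    vals = volume.data[m]
    if vals.size == 0:
        raise ValidationError("empty ROI")
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(volume.shape, dtype=np.int32)
    if hi - lo <= 0:
        levels[m] = 1
        return DiscretizedROI(levels=levels, n_levels=1, mask=m, spacing=np.asarray(volume.spacing))
    w = (hi - lo) / n_bins
    lev = np.minimum(np.floor((volume.data[m] - lo) / w).astype(np.int32) + 1, n_bins)
    levels[m] = lev
    return DiscretizedROI(levels=levels, n_levels=n_bins, mask=m, spacing=np.asarray(volume.spacing))
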