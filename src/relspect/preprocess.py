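"""Intensity scaling, specific binding ratio, and canonical mirroring.

The three steps performed on every scan before classification:

1. ``scale_to_reference`` divides the volume by the 75th percentile of the
   intensities inside the reference region (whole brain minus striata), so
   nonspecific uptake reads ~1 in every scan.
2. ``compute_sbr`` estimates the specific binding ratio of a target
   structure by hottest-voxels analysis on a slightly enlarged mask:
   SBR = mean(hottest voxels) - 1, with the reference level pinned to 1 by
   step 1.
3. ``mirror_to_canonical`` flips scans left-right about the midsagittal
   plane whenever the right putaminal SBR is lower, so the more-affected
   ("ipsilateral") putamen is on the left in every scan the classifier sees.

Percentiles use linear interpolation between order statistics; mirroring
ties (exactly equal SBRs) are resolved as "no flip" for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation

from .io_volumes import RoiSet, SpectVolume

__all__ = [
    "SbrResult",
    "scale_to_reference",
    "compute_sbr",
    "mirror_to_canonical",
    "DEFAULT_HOTTEST_FRACTION",
    "DEFAULT_ROI_DILATION",
]

#: Fraction of the enlarged target mask averaged in hottest-voxels analysis.
DEFAULT_HOTTEST_FRACTION = 0.25
#: Dilation (voxels) producing the "large" target ROI.
DEFAULT_ROI_DILATION = 1


class DegenerateInputError(ValueError):
    """Raised when the reference region cannot define a positive scale."""


@dataclass(frozen=True)
class SbrResult:
    """Left/right putaminal SBR of one scan plus the scaling denominator."""

    sbr_left: float
    sbr_right: float
    reference_value: float
    n_hottest: int

    def __post_init__(self):
        if self.reference_value <= 0:
            raise DegenerateInputError("reference_value must be positive")
        if self.n_hottest < 1:
            raise ValueError("n_hottest must be >= 1")

    @property
    def sbr_min(self) -> float:
        return min(self.sbr_left, self.sbr_right)


def scale_to_reference(vol: SpectVolume, rois: RoiSet) -> SpectVolume:
    """Divide by the 75th percentile of the reference-region intensities.

    After scaling, that percentile of the output's reference voxels is
    exactly 1; the operation is idempotent and invariant under global
    rescaling of the input.
    """
    rois.check_geometry(vol)
    ref_vals = vol.data[rois["reference"]]
    divisor = float(np.percentile(ref_vals, 75))
    if divisor <= 0:
        raise DegenerateInputError(
            f"75th percentile of reference region is {divisor}; cannot scale"
        )
    out = vol.with_data(vol.data / divisor)
    out.metadata = {**vol.metadata, "reference_value": divisor}
    return out


def _enlarged(mask: np.ndarray, dilate: int) -> np.ndarray:
    if dilate <= 0:
        return mask
    return binary_dilation(mask, iterations=dilate)


def compute_sbr(
    vol: SpectVolume,
    target_mask: np.ndarray,
    hottest_fraction: float = DEFAULT_HOTTEST_FRACTION,
    dilate: int = DEFAULT_ROI_DILATION,
) -> float:
    """Hottest-voxels specific binding ratio of ``target_mask``.

    The target mask is dilated by ``dilate`` voxels (the "large" ROI), the
    hottest ``ceil(hottest_fraction * |large ROI|)`` voxels are averaged,
    and 1 (the reference level of a scaled volume) is subtracted:
    SBR = (hottest mean - reference) / reference with reference = 1.

    ``vol`` must already be scaled by :func:`scale_to_reference`.
    """
    target_mask = np.asarray(target_mask, dtype=bool)
    if target_mask.shape != vol.shape:
        from .io_volumes import GeometryError

        raise GeometryError(
            f"mask grid {target_mask.shape} != volume grid {vol.shape}"
        )
    if not target_mask.any():
        raise ValueError("target mask is empty")
    if not 0.0 < hottest_fraction <= 1.0:
        raise ValueError("hottest_fraction must be in (0, 1]")
    big = _enlarged(target_mask, dilate)
    vals = vol.data[big]
    k = int(np.ceil(hottest_fraction * vals.size))
    hottest = np.sort(vals)[-k:]
    return float(hottest.mean() - 1.0)


def putaminal_sbrs(
    vol: SpectVolume,
    rois: RoiSet,
    hottest_fraction: float = DEFAULT_HOTTEST_FRACTION,
    dilate: int = DEFAULT_ROI_DILATION,
) -> SbrResult:
    """Left and right putaminal SBR of a scaled volume.

    "Left" refers to the grid's low-x half (the ``putamen_ipsi`` mask of the
    canonical ROI set), independent of any mirrored state.
    """
    rois.check_geometry(vol)
    big = _enlarged(rois["putamen_ipsi"], dilate)
    k = int(np.ceil(hottest_fraction * int(big.sum())))
    return SbrResult(
        sbr_left=compute_sbr(vol, rois["putamen_ipsi"], hottest_fraction, dilate),
        sbr_right=compute_sbr(vol, rois["putamen_contra"], hottest_fraction, dilate),
        reference_value=float(vol.metadata.get("reference_value", 1.0)),
        n_hottest=k,
    )


def mirror_to_canonical(
    vol: SpectVolume,
    rois: RoiSet,
    hottest_fraction: float = DEFAULT_HOTTEST_FRACTION,
    dilate: int = DEFAULT_ROI_DILATION,
):
    """Flip the scan so the lower-SBR putamen is on the left.

    Returns ``(volume, SbrResult)`` where the SBRs describe the *returned*
    volume.  If the right putaminal SBR is strictly lower than the left, the
    volume is mirrored about the midline plane x = (nx-1)/2 and its
    ``mirrored`` flag set; an exact tie leaves the scan unchanged.  The flip
    is an isometry: the voxel multiset is preserved.
    """
    sbr = putaminal_sbrs(vol, rois, hottest_fraction, dilate)
    if sbr.sbr_right < sbr.sbr_left:
        vol = vol.flipped_lr()
        sbr = SbrResult(
            sbr_left=sbr.sbr_right,
            sbr_right=sbr.sbr_left,
            reference_value=sbr.reference_value,
            n_hottest=sbr.n_hottest,
        )
    return vol, sbr
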