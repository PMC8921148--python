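"""Group-level relevance analytics and relevance-based re-classification.

Given per-case relevance maps and the CNN's predictions, this module
computes the group mean maps of true-negative and true-positive cases, the
"heat map" (their voxel-wise difference, oriented mean(TP) - mean(TN)), the
putaminal mean relevance of each scan by the same hottest-voxels analysis
used for the binding ratio, the zero-cutoff relevance classifier built on
that statistic, and the "inconsistent map" flag for scans whose putaminal
relevance sign contradicts the CNN's predicted class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.ndimage import binary_dilation

from .io_volumes import GeometryError, RoiSet
from .lrp import RelevanceMap
from .preprocess import DEFAULT_HOTTEST_FRACTION, DEFAULT_ROI_DILATION

__all__ = [
    "GroupRelevanceSummary",
    "PutaminalRelevance",
    "mean_relevance_map",
    "heat_map",
    "putaminal_mean_relevance",
    "classify_by_relevance",
    "flag_inconsistent",
    "summarize_groups",
]


@dataclass
class GroupRelevanceSummary:
    """Mean relevance maps per outcome group and their difference."""

    mean_map_tn: np.ndarray
    mean_map_tp: np.ndarray
    heat_map: np.ndarray
    n_tn: int
    n_tp: int


@dataclass(frozen=True)
class PutaminalRelevance:
    """Signed mean relevance in the enlarged ipsilateral putamen ROI."""

    value: float
    case_id: object = None
    cnn_prediction: Optional[str] = None
    truth_label: Optional[str] = None

    def __post_init__(self):
        if not np.isfinite(self.value):
            raise ValueError("putaminal relevance must be finite")


def _map_data(m) -> np.ndarray:
    return m.data if isinstance(m, RelevanceMap) else np.asarray(m)


def mean_relevance_map(maps: Sequence) -> np.ndarray:
    """Voxel-wise arithmetic mean of a group of relevance maps."""
    arrays = [_map_data(m) for m in maps]
    if len(arrays) == 0:
        raise ValueError("empty group of relevance maps")
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise GeometryError(f"relevance maps on mismatched grids: {shapes}")
    return np.mean(arrays, axis=0)


def heat_map(mean_tp: np.ndarray, mean_tn: np.ndarray) -> np.ndarray:
    """Difference of the group mean maps, mean(TP) - mean(TN).

    With positive true-positive putaminal relevance this orientation makes
    the ipsilateral putamen the hottest region.
    """
    mean_tp = np.asarray(mean_tp)
    mean_tn = np.asarray(mean_tn)
    if mean_tp.shape != mean_tn.shape:
        raise GeometryError(
            f"mean maps on mismatched grids: {mean_tp.shape} vs {mean_tn.shape}"
        )
    return mean_tp - mean_tn


def summarize_groups(maps: Sequence, truth: Sequence[str], predictions: Sequence[str]):
    """Group summary over the correctly classified cases.

    Returns a :class:`GroupRelevanceSummary` with the TN and TP mean maps
    and the heat map.
    """
    maps = list(maps)
    tn = [m for m, t, p in zip(maps, truth, predictions) if t == p == "negative"]
    tp = [m for m, t, p in zip(maps, truth, predictions) if t == p == "positive"]
    if not tn or not tp:
        raise ValueError("need at least one true negative and one true positive")
    mean_tn = mean_relevance_map(tn)
    mean_tp = mean_relevance_map(tp)
    return GroupRelevanceSummary(
        mean_map_tn=mean_tn,
        mean_map_tp=mean_tp,
        heat_map=heat_map(mean_tp, mean_tn),
        n_tn=len(tn),
        n_tp=len(tp),
    )


def putaminal_mean_relevance(
    rmap,
    rois: RoiSet,
    hottest_fraction: float = DEFAULT_HOTTEST_FRACTION,
    dilate: int = DEFAULT_ROI_DILATION,
    rank_by_abs: bool = True,
    case_id=None,
    cnn_prediction: Optional[str] = None,
    truth_label: Optional[str] = None,
) -> PutaminalRelevance:
    """Hottest-voxels mean relevance in the ipsilateral putamen.

    The same enlarged-ROI / hottest-fraction analysis as the binding-ratio
    estimate, applied to the sign-harmonized relevance map.  Because
    relevance is signed, "hottest" ranks voxels by absolute relevance by
    default (``rank_by_abs=False`` ranks by raw value); the mean is taken
    over the *signed* values of the selected voxels either way.
    """
    data = _map_data(rmap)
    if data.shape != rois.shape:
        raise GeometryError(f"map grid {data.shape} != ROI grid {rois.shape}")
    mask = rois["putamen_ipsi"]
    if dilate > 0:
        mask = binary_dilation(mask, iterations=dilate)
    vals = data[mask]
    if vals.size == 0:
        raise ValueError("empty putamen ROI")
    k = int(np.ceil(hottest_fraction * vals.size))
    order = np.argsort(np.abs(vals) if rank_by_abs else vals)
    selected = vals[order[-k:]]
    return PutaminalRelevance(
        value=float(selected.mean()),
        case_id=case_id,
        cnn_prediction=cnn_prediction,
        truth_label=truth_label,
    )


def classify_by_relevance(pr, cutoff: float = 0.0) -> str:
    """Dichotomize putaminal mean relevance at the cutoff (default zero).

    Positive relevance indicates a positive (reduced) scan; the tie
    ``value == cutoff`` is declared negative.
    """
    value = pr.value if isinstance(pr, PutaminalRelevance) else float(pr)
    return "positive" if value > cutoff else "negative"


def flag_inconsistent(pr, cnn_prediction: str, cutoff: float = 0.0) -> bool:
    """True iff the relevance-based class contradicts the CNN prediction.

    An inconsistent map (e.g. a CNN-negative scan with clearly positive
    putaminal relevance) is a candidate misclassification.
    """
    if cnn_prediction not in ("negative", "positive"):
        raise ValueError(f"unknown prediction {cnn_prediction!r}")
    return classify_by_relevance(pr, cutoff) != cnn_prediction
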