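"""Synthetic striatal phantom: already-normalized DAT-SPECT-like volumes.

The generator emulates the *appearance* of stereotactically normalized,
intensity-scaled dopamine-transporter SPECT, not its physics: a brain
ellipsoid of uniform nonspecific background, bilateral ellipsoidal putamen
and caudate compartments carrying specific binding on top of the background,
Gaussian blur standing in for reconstructed SPECT resolution, and
intensity-proportional Gaussian noise standing in for reconstructed count
noise.  Nigrostriatal degeneration is modelled as a fractional loss of the
specific putaminal (and, attenuated, caudate) signal, applied asymmetrically
between hemispheres as in typical Lewy-body disease.

Geometry is defined in millimetres, so the same object can be sampled on the
default 48x56x44 grid at 3 mm or on coarser grids (the field of view is
144x168x132 mm either way).  The putamen-caudate gap is deliberately wider
than the anatomical internal capsule so that, even after the 12 mm FWHM
point-spread blur, a fully denervated putamen with spared caudate reads a
putaminal specific binding ratio near zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter

from .io_volumes import GeometryError, RoiSet, SpectVolume

__all__ = [
    "PhantomParams",
    "LabeledCase",
    "LabeledDataset",
    "make_phantom_rois",
    "simulate_case",
    "simulate_cohort",
]

# Ellipsoid geometry in mm, relative to the grid centre; x < 0 is the left
# hemisphere.  The brain ellipsoid bounds the nonspecific background.
_BRAIN_SEMI = (60.0, 75.0, 57.0)
_PUTAMEN_CENTER = (27.0, -4.0, -5.0)   # |x| offset; mirrored for left/right
_PUTAMEN_SEMI = (8.0, 15.0, 10.0)
_CAUDATE_CENTER = (10.0, 26.0, 12.0)
_CAUDATE_SEMI = (5.0, 10.0, 8.0)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class PhantomParams:
    """Parameters of one simulated case.

    ``severity`` is the fractional loss of specific putaminal binding in the
    more-affected hemisphere (0 = normal, 1 = complete loss).  ``asymmetry``
    is the ratio of the loss in the less-affected to the more-affected
    hemisphere (1 = symmetric disease, 0 = strictly unilateral).
    ``caudate_sparing`` is the fraction of the (per-hemisphere) putaminal
    severity that applies to the caudate; the caudate is affected later and
    less than the putamen in nigrostriatal degeneration.
    """

    grid_shape: tuple = (48, 56, 44)
    voxel_size: float = 3.0
    background_level: float = 1.0
    striatal_contrast_normal: float = 2.5   # mean of the per-case contrast draw
    contrast_sd: float = 0.3
    severity: float = 0.0
    asymmetry: float = 0.5
    caudate_sparing: float = 0.5
    psf_fwhm: float = 12.0                  # mm, Gaussian resolution blur
    noise_sd: float = 0.05                  # relative (intensity-proportional)
    seed: int = 0

    def __post_init__(self):
        for name in ("severity", "asymmetry", "caudate_sparing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.background_level <= 0:
            raise ValueError("background_level must be positive")
        if self.noise_sd < 0 or self.psf_fwhm < 0:
            raise ValueError("noise_sd and psf_fwhm must be non-negative")


@dataclass
class LabeledCase:
    """One simulated scan with its ground-truth label and draw record."""

    volume: SpectVolume
    label: str                       # "negative" | "positive"
    truth: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)  # age (years), sex ("F"/"M")

    def __post_init__(self):
        if self.label not in ("negative", "positive"):
            raise ValueError(f"unknown label {self.label!r}")


@dataclass
class LabeledDataset:
    """Ordered collection of labeled cases with generation provenance."""

    cases: list
    provenance: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.cases)

    def __iter__(self):
        return iter(self.cases)

    def __getitem__(self, i):
        return self.cases[i]

    @property
    def labels(self) -> np.ndarray:
        return np.array([c.label for c in self.cases])

    @property
    def ages(self) -> np.ndarray:
        return np.array([c.metadata.get("age", np.nan) for c in self.cases])

    @property
    def sexes(self) -> np.ndarray:
        return np.array([c.metadata.get("sex", "?") for c in self.cases])


def _mm_grids(grid_shape, voxel_size):
    vs = np.broadcast_to(np.atleast_1d(voxel_size), (3,)).astype(float)
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * v for n, v in zip(grid_shape, vs)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(grids, center, semi) -> np.ndarray:
    x, y, z = grids
    cx, cy, cz = center
    ax, ay, az = semi
    return (
        ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2
    ) <= 1.0


def make_phantom_rois(grid_shape=(48, 56, 44), voxel_size=3.0) -> RoiSet:
    """Build the phantom's ROI set on the requested grid.

    Ipsi/contra follow the canonical convention (ipsilateral = left = low x
    index).  The reference region is the brain ellipsoid minus the striatum
    dilated by 2 voxels, emulating a whole-brain-minus-striata reference.

    Raises
    ------
    GeometryError
        If the grid is too small/coarse to contain the structures.
    """
    vs = float(np.atleast_1d(voxel_size).ravel()[0])
    grids = _mm_grids(grid_shape, vs)
    masks = {}
    put_l = _ellipsoid(grids, (-_PUTAMEN_CENTER[0],) + _PUTAMEN_CENTER[1:], _PUTAMEN_SEMI)
    put_r = _ellipsoid(grids, _PUTAMEN_CENTER, _PUTAMEN_SEMI)
    cau_l = _ellipsoid(grids, (-_CAUDATE_CENTER[0],) + _CAUDATE_CENTER[1:], _CAUDATE_SEMI)
    cau_r = _ellipsoid(grids, _CAUDATE_CENTER, _CAUDATE_SEMI)
    brain = _ellipsoid(grids, (0.0, 0.0, 0.0), _BRAIN_SEMI)
    striatum = put_l | put_r | cau_l | cau_r
    reference = brain & ~binary_dilation(striatum, iterations=2)
    masks = {
        "putamen_ipsi": put_l,
        "putamen_contra": put_r,
        "caudate_ipsi": cau_l,
        "caudate_contra": cau_r,
        "striatum": striatum,
        "reference": reference,
    }
    for name, m in masks.items():
        if not m.any():
            raise GeometryError(
                f"grid {grid_shape} at {voxel_size} mm too small: '{name}' empty"
            )
    overlap = (
        put_l.astype(int) + put_r.astype(int) + cau_l.astype(int) + cau_r.astype(int)
    )
    if overlap.max() > 1:
        raise GeometryError("phantom structures overlap on this grid")
    return RoiSet(masks, voxel_size=(vs,) * 3)


def brain_mask(grid_shape=(48, 56, 44), voxel_size=3.0) -> np.ndarray:
    """Boolean mask of the phantom's brain ellipsoid."""
    return _ellipsoid(_mm_grids(grid_shape, voxel_size), (0.0, 0.0, 0.0), _BRAIN_SEMI)


def simulate_case(params: PhantomParams, rois: Optional[RoiSet] = None) -> LabeledCase:
    """Simulate one scan from the piecewise intensity model.

    The noiseless model assigns ``background_level`` inside the brain and
    raises each striatal compartment by ``background * contrast * (1 -
    applicable severity)``; the grid is then blurred with the Gaussian PSF
    and intensity-proportional Gaussian noise is added.  The more-affected
    hemisphere is drawn at random and recorded in ``truth``.  Deterministic
    given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    if rois is None:
        rois = make_phantom_rois(params.grid_shape, params.voxel_size)
    affected_side = "left" if rng.random() < 0.5 else "right"
    contrast = float(
        np.clip(
            rng.normal(params.striatal_contrast_normal, params.contrast_sd),
            1.0,
            None,
        )
    )

    sev_more = params.severity
    sev_less = params.severity * params.asymmetry
    # canonical masks: ipsi = left on the unmirrored phantom grid
    side_of = {"left": "ipsi", "right": "contra"}
    sev = {side_of[affected_side]: sev_more}
    sev[side_of["right" if affected_side == "left" else "left"]] = sev_less

    bg = params.background_level
    vol = np.where(
        brain_mask(params.grid_shape, params.voxel_size), bg, 0.0
    ).astype(np.float64)
    for side in ("ipsi", "contra"):
        vol[rois[f"putamen_{side}"]] += bg * contrast * (1.0 - sev[side])
        vol[rois[f"caudate_{side}"]] += (
            bg * contrast * (1.0 - params.caudate_sparing * sev[side])
        )

    if params.psf_fwhm > 0:
        sigma = params.psf_fwhm * FWHM_TO_SIGMA / np.asarray(
            np.broadcast_to(np.atleast_1d(params.voxel_size), (3,)), dtype=float
        )
        vol = gaussian_filter(vol, sigma=sigma, mode="constant")
    if params.noise_sd > 0:
        vol = vol + vol * params.noise_sd * rng.standard_normal(vol.shape)

    label = "positive" if params.severity > 0 else "negative"
    volume = SpectVolume(
        vol, (float(np.atleast_1d(params.voxel_size)[0]),) * 3
    )
    truth = {
        "params": asdict(params),
        "affected_side": affected_side,
        "contrast": contrast,
        "severity_more": sev_more,
        "severity_less": sev_less,
    }
    return LabeledCase(volume=volume, label=label, truth=truth)


def simulate_cohort(
    n: int,
    positive_fraction: float = 0.478,
    seed: int = 0,
    base_params: Optional[PhantomParams] = None,
    severity_floor: float = 0.2,
    borderline_fraction: float = 0.0,
    age_mean: float = 67.5,
    age_sd: float = 11.0,
    female_fraction: float = 0.42,
) -> LabeledDataset:
    """Simulate a labelled cohort with demographics.

    The number of positives is ``floor(n * positive_fraction)``.  Positive
    cases draw their severity uniformly from ``[severity_floor, 1]`` (a
    floor keeps labels from being dominated by near-boundary cases); a
    ``borderline_fraction`` of positives instead draws severity near 0.1 to
    emulate borderline scans.  Ages are normal(age_mean, age_sd), sex is
    Bernoulli(female_fraction); both exist only to exercise the stratified
    split and do not influence the intensity model.  Per-case seeds are
    derived from the master seed, so the cohort is a pure function of its
    arguments.
    """
    if n < 4:
        raise ValueError("cohort size must be >= 4")
    if not 0.0 <= positive_fraction <= 1.0:
        raise ValueError(f"positive_fraction must be in [0, 1], got {positive_fraction}")
    if base_params is None:
        base_params = PhantomParams()
    rng = np.random.default_rng(seed)
    n_pos = int(np.floor(n * positive_fraction))
    labels = np.array(["positive"] * n_pos + ["negative"] * (n - n_pos))
    rng.shuffle(labels)
    case_seeds = (
        np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64) % (2**31)
    ).astype(np.int64)
    ages = rng.normal(age_mean, age_sd, size=n)
    sexes = np.where(rng.random(n) < female_fraction, "F", "M")
    rois = make_phantom_rois(base_params.grid_shape, base_params.voxel_size)

    cases = []
    for i in range(n):
        if labels[i] == "positive":
            if borderline_fraction > 0 and rng.random() < borderline_fraction:
                severity = float(rng.uniform(0.05, 0.15))
            else:
                severity = float(rng.uniform(severity_floor, 1.0))
        else:
            severity = 0.0
        params = replace(base_params, severity=severity, seed=int(case_seeds[i]))
        case = simulate_case(params, rois=rois)
        case.metadata = {"age": float(ages[i]), "sex": str(sexes[i]), "case_id": i}
        cases.append(case)
    provenance = {
        "n": n,
        "positive_fraction": positive_fraction,
        "seed": seed,
        "severity_floor": severity_floor,
        "borderline_fraction": borderline_fraction,
        "base_params": asdict(base_params),
    }
    return LabeledDataset(cases=cases, provenance=provenance)
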