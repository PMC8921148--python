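"""Volume and ROI input/output in NIfTI, plus relevance-map serialization.

All volumes handled by this package live on a single canonical grid with a
fixed axis order: x = left -> right (neurological convention), y = posterior
-> anterior, z = inferior -> superior.  The left hemisphere therefore
occupies x-indices below the grid midline ``(nx - 1) / 2``.  Files are
reoriented to this convention on read (via the closest-canonical RAS+
transform) so that downstream mirroring and "ipsilateral" semantics are
unambiguous.

Relevance maps are stored as ordinary signed floating-point NIfTI volumes;
per-volume metadata (class label, mirrored flag, prediction, conservation
diagnostics, ...) travels in a JSON sidecar next to the image file so that
third-party viewers can overlay maps without custom readers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Mapping, Optional

import nibabel as nib
import numpy as np

__all__ = [
    "SpectVolume",
    "RoiSet",
    "ROI_NAMES",
    "read_volume",
    "write_volume",
    "load_roi_set",
    "sidecar_path",
]

#: Mask names required in every :class:`RoiSet`.
ROI_NAMES = (
    "putamen_ipsi",
    "putamen_contra",
    "caudate_ipsi",
    "caudate_contra",
    "striatum",
    "reference",
)


class VolumeFormatError(ValueError):
    """Raised for unreadable files or wrong dimensionality."""


class GeometryError(ValueError):
    """Raised when grids of volumes/masks in one analysis do not match."""


class RoiInvariantError(ValueError):
    """Raised when an ROI set violates its structural invariants."""


@dataclass
class SpectVolume:
    """A 3D uptake volume on the canonical grid.

    Parameters
    ----------
    data:
        3D array of finite intensities (arbitrary uptake units).
    voxel_size:
        Edge length per axis in millimetres.
    mirrored:
        Whether the volume has been left-right flipped into canonical
        laterality (lower putaminal binding on the left).
    metadata:
        Free-form JSON-serializable dictionary (label, SBR values, ...).
    """

    data: np.ndarray
    voxel_size: tuple
    mirrored: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise VolumeFormatError(
                f"expected 3D data, got {self.data.ndim}D"
            )
        if min(self.data.shape) < 8:
            raise VolumeFormatError(
                f"all dimensions must be >= 8 voxels, got {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise VolumeFormatError("volume contains non-finite intensities")
        vs = tuple(float(v) for v in np.atleast_1d(self.voxel_size).ravel())
        if len(vs) == 1:
            vs = vs * 3
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise VolumeFormatError(f"invalid voxel size {self.voxel_size}")
        self.voxel_size = vs

    @property
    def shape(self):
        return self.data.shape

    def with_data(self, data: np.ndarray, **changes) -> "SpectVolume":
        """Copy of this volume with new voxel data (same geometry)."""
        return replace(self, data=data, **changes)

    def flipped_lr(self) -> "SpectVolume":
        """Mirror about the midsagittal grid plane x = (nx-1)/2.

        Reversing the x axis is an exact involution for any nx (even nx
        flips about the half-voxel boundary).
        """
        return replace(
            self, data=self.data[::-1, :, :].copy(), mirrored=not self.mirrored
        )


@dataclass
class RoiSet:
    """Named binary masks on one grid (see :data:`ROI_NAMES`).

    Invariants (checked on construction): masks are nonempty and share one
    shape; the four putamen/caudate masks are pairwise disjoint; striatum
    equals their union; the reference mask is disjoint from the striatum.
    """

    masks: Dict[str, np.ndarray]
    voxel_size: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        missing = set(ROI_NAMES) - set(self.masks)
        if missing:
            raise RoiInvariantError(f"missing masks: {sorted(missing)}")
        masks = {k: np.asarray(v, dtype=bool) for k, v in self.masks.items()}
        shapes = {m.shape for m in masks.values()}
        if len(shapes) != 1:
            raise GeometryError(f"masks on mismatched grids: {shapes}")
        for name, m in masks.items():
            if not m.any():
                raise RoiInvariantError(f"mask '{name}' is empty")
        parts = ["putamen_ipsi", "putamen_contra", "caudate_ipsi", "caudate_contra"]
        count = sum(masks[p].astype(int) for p in parts)
        if count.max() > 1:
            raise RoiInvariantError("putamen/caudate masks overlap")
        union = count > 0
        if not np.array_equal(union, masks["striatum"]):
            raise RoiInvariantError("striatum != union of putamen and caudate masks")
        if np.any(masks["reference"] & masks["striatum"]):
            raise RoiInvariantError("reference mask overlaps striatum")
        self.masks = masks
        vs = tuple(float(v) for v in np.atleast_1d(self.voxel_size).ravel())
        if len(vs) == 1:
            vs = vs * 3
        self.voxel_size = vs

    @property
    def shape(self):
        return next(iter(self.masks.values())).shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def check_geometry(self, vol: SpectVolume) -> None:
        """Fail loudly if ``vol`` is not on this ROI grid."""
        if vol.shape != self.shape:
            raise GeometryError(
                f"volume grid {vol.shape} != ROI grid {self.shape}"
            )


def _canonical_affine(voxel_size) -> np.ndarray:
    aff = np.diag(list(voxel_size) + [1.0])
    return aff


def sidecar_path(path) -> Path:
    """JSON sidecar path for a NIfTI file (``vol.nii.gz`` -> ``vol.json``)."""
    p = Path(path)
    name = p.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
            break
    return p.with_name(name + ".json")


def write_volume(vol: SpectVolume, path, sidecar: bool = True) -> None:
    """Write a volume (or signed relevance map) to NIfTI.

    The canonical orientation is recorded in the affine (RAS+, scaled by the
    voxel size).  When ``sidecar`` is true, a JSON sidecar with the mirrored
    flag and any metadata is written alongside.
    """
    path = Path(path)
    img = nib.Nifti1Image(
        np.asarray(vol.data, dtype=np.float32), _canonical_affine(vol.voxel_size)
    )
    img.header.set_zooms(vol.voxel_size)
    try:
        nib.save(img, str(path))
    except OSError as exc:  # pragma: no cover - filesystem dependent
        raise IOError(f"could not write volume to {path}: {exc}") from exc
    if sidecar:
        meta = {"mirrored": bool(vol.mirrored), **vol.metadata}
        sidecar_path(path).write_text(json.dumps(meta, indent=1, default=float))


def read_volume(path) -> SpectVolume:
    """Read a NIfTI volume, reoriented to the canonical axis order.

    Raises
    ------
    VolumeFormatError
        For unreadable files or non-3D data.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise VolumeFormatError(f"could not read {path}: {exc}") from exc
    if len(img.shape) != 3:
        raise VolumeFormatError(
            f"expected 3D volume, file has shape {img.shape}"
        )
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    meta: dict = {}
    sp = sidecar_path(path)
    if sp.exists():
        meta = json.loads(sp.read_text())
    mirrored = bool(meta.pop("mirrored", False))
    return SpectVolume(data, voxel_size, mirrored=mirrored, metadata=meta)


def _load_mask(path) -> np.ndarray:
    vol = read_volume(path)
    return vol.data > 0.5


def load_roi_set(source, grid_shape=None, voxel_size=None) -> RoiSet:
    """Load an ROI set from a directory of NIfTI masks or a builtin name.

    ``source`` may be the builtin name ``"phantom_default"`` (the masks of
    the bundled striatal phantom, optionally at a caller-supplied
    ``grid_shape``/``voxel_size``) or a directory containing one
    ``<name>.nii[.gz]`` file per mask in :data:`ROI_NAMES`.
    """
    if isinstance(source, str) and source == "phantom_default":
        from .phantom import PhantomParams, make_phantom_rois

        defaults = PhantomParams()
        return make_phantom_rois(
            grid_shape or defaults.grid_shape, voxel_size or defaults.voxel_size
        )
    src = Path(source)
    if not src.is_dir():
        raise VolumeFormatError(f"no such ROI directory or builtin: {source}")
    masks = {}
    vs = None
    for name in ROI_NAMES:
        candidates = [src / f"{name}.nii.gz", src / f"{name}.nii"]
        found = next((c for c in candidates if c.exists()), None)
        if found is None:
            raise RoiInvariantError(f"mask file for '{name}' not found in {src}")
        vol = read_volume(found)
        masks[name] = vol.data > 0.5
        vs = vol.voxel_size
    return RoiSet(masks, voxel_size=vs)
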