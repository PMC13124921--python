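"""Volume containers, NIfTI I/O, upsampling, and tissue-mask construction.

Volumes are 3-D scalar grids with a voxel-to-world affine.  Masks derived
from probabilistic tissue maps use strict (>) threshold comparisons: a voxel
belongs to the parenchyma when the summed GM+WM probability *exceeds* the
threshold, and to a pure-tissue mask when its single-tissue probability
exceeds the (higher) purity threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Tuple

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import InvalidArgumentError, InvalidInputError

VOLUME_KINDS = ("suv", "suvr", "probability", "label")

#: interpolation scheme name -> spline order for scipy.ndimage
_INTERP_ORDERS = {"nearest": 0, "linear": 1, "cubic": 3}

#: affine agreement tolerance when checking that two volumes share a grid (mm)
GRID_ATOL_MM = 1e-4


@dataclass
class ScalarVolume:
    """A 3-D grid of real values with voxel geometry.

    Parameters
    ----------
    data
        3-D array of finite values (integers for ``kind='label'``).
    affine
        4x4 voxel-index -> world-mm transform (NIfTI convention).
    kind
        One of ``{'suv', 'suvr', 'probability', 'label'}``.
    """

    data: np.ndarray
    affine: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise InvalidInputError(f"volume must be 3-D, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise InvalidInputError("affine must be 4x4")
        if self.kind not in VOLUME_KINDS:
            raise InvalidArgumentError(f"unknown volume kind {self.kind!r}")
        if self.kind == "label":
            if not np.issubdtype(self.data.dtype, np.integer):
                rounded = np.rint(self.data)
                if not np.allclose(self.data, rounded, atol=1e-6, equal_nan=False):
                    raise InvalidInputError("label volume has non-integer values")
                self.data = rounded.astype(np.int32)
            if self.data.min() < 0:
                raise InvalidInputError("label volume has negative labels")
        else:
            self.data = self.data.astype(np.float64, copy=False)
            if not np.all(np.isfinite(self.data)):
                raise InvalidInputError("volume contains non-finite values")
            if self.kind == "probability":
                if self.data.min() < -1e-9 or self.data.max() > 1 + 1e-9:
                    raise InvalidInputError("probability volume has values outside [0, 1]")
                self.data = np.clip(self.data, 0.0, 1.0)
        if np.any(self.voxel_size_mm <= 0):
            raise InvalidInputError("voxel sizes must be positive")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Physical voxel spacing: column norms of the affine's linear part."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @classmethod
    def from_voxel_size(
        cls, data: np.ndarray, voxel_size_mm, kind: str
    ) -> "ScalarVolume":
        """Build a volume with a diagonal affine from a voxel-size triple."""
        vs = np.asarray(voxel_size_mm, dtype=float)
        affine = np.diag([vs[0], vs[1], vs[2], 1.0])
        return cls(data=data, affine=affine, kind=kind)

    def with_data(self, data: np.ndarray, kind: str | None = None) -> "ScalarVolume":
        return ScalarVolume(data=data, affine=self.affine.copy(), kind=kind or self.kind)

    def same_grid(self, other: "ScalarVolume", atol: float = GRID_ATOL_MM) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


@dataclass
class BinaryMask:
    """A boolean voxel-selection grid plus its bookkeeping invariants."""

    data: np.ndarray
    source_shape: Tuple[int, int, int]
    voxel_count: int = field(default=-1)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        self.source_shape = tuple(self.source_shape)
        if self.data.shape != self.source_shape:
            raise InvalidInputError(
                f"mask shape {self.data.shape} != source shape {self.source_shape}"
            )
        n = int(self.data.sum())
        if self.voxel_count < 0:
            self.voxel_count = n
        elif self.voxel_count != n:
            raise InvalidInputError("voxel_count inconsistent with mask data")

    @classmethod
    def from_array(cls, data: np.ndarray) -> "BinaryMask":
        data = np.asarray(data, dtype=bool)
        return cls(data=data, source_shape=data.shape)


def resample_upsample(
    volume: ScalarVolume, factor: int, method: str = "cubic"
) -> ScalarVolume:
    """Upsample a volume by an integer factor per axis.

    Output voxel ``j`` samples the input at continuous index ``j / factor``,
    so original lattice points (``j = factor * i``) reproduce the input values
    exactly, voxel size is divided by ``factor``, and the adjusted affine
    preserves world coordinates.  Probability volumes are clipped to [0, 1]
    after interpolation; label volumes always use nearest-neighbour.
    """
    if int(factor) != factor or factor < 1:
        raise InvalidArgumentError(f"upsampling factor must be a positive integer, got {factor}")
    factor = int(factor)
    if method not in _INTERP_ORDERS:
        raise InvalidArgumentError(f"unknown interpolation method {method!r}")
    if volume.kind != "label" and not np.all(np.isfinite(volume.data)):
        raise InvalidInputError("volume contains non-finite values")

    if factor == 1:
        return ScalarVolume(volume.data.copy(), volume.affine.copy(), volume.kind)

    order = 0 if volume.kind == "label" else _INTERP_ORDERS[method]
    out_shape = tuple(s * factor for s in volume.shape)
    coords = np.meshgrid(
        *(np.arange(n, dtype=float) / factor for n in out_shape), indexing="ij"
    )
    src = volume.data.astype(np.float64, copy=False)
    out = ndimage.map_coordinates(src, coords, order=order, mode="nearest")

    scale = np.diag([1.0 / factor] * 3 + [1.0])
    new_affine = volume.affine @ scale

    if volume.kind == "probability":
        out = np.clip(out, 0.0, 1.0)
    if volume.kind == "label":
        out = np.rint(out).astype(np.int32)
    return ScalarVolume(data=out, affine=new_affine, kind=volume.kind)


def make_parenchyma_mask(
    p_gm: ScalarVolume, p_wm: ScalarVolume, threshold: float = 0.5
) -> BinaryMask:
    """Voxels where GM + WM probability strictly exceeds ``threshold``.

    The strict comparison excludes the CSF space and boundary voxels whose
    summed probability equals the threshold exactly.
    """
    if p_gm.kind != "probability" or p_wm.kind != "probability":
        raise InvalidInputError("parenchyma mask requires probability volumes")
    if not p_gm.same_grid(p_wm):
        raise InvalidInputError("GM and WM probability maps are not on the same grid")
    return BinaryMask.from_array((p_gm.data + p_wm.data) > threshold)


def make_tissue_mask(p: ScalarVolume, threshold: float = 0.6) -> BinaryMask:
    """Voxels where a single-tissue probability strictly exceeds ``threshold``."""
    if not (0.0 <= threshold <= 1.0):
        raise InvalidArgumentError(f"tissue threshold must lie in [0, 1], got {threshold}")
    if p.kind != "probability":
        raise InvalidInputError("tissue mask requires a probability volume")
    return BinaryMask.from_array(p.data > threshold)


def load_volume(path, kind: str) -> ScalarVolume:
    """Read a NIfTI-1 volume from disk."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input volume not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if kind == "label":
        data = np.rint(np.asarray(data, dtype=float)).astype(np.int32)
    else:
        data = np.asarray(data, dtype=np.float64)
    return ScalarVolume(data=data, affine=np.asarray(img.affine), kind=kind)


def save_volume(volume: ScalarVolume, path) -> None:
    """Write a volume as NIfTI-1 (labels as int32, the rest as float64)."""
    data = volume.data
    if volume.kind == "label":
        data = data.astype(np.int32)
    img = nib.Nifti1Image(data, volume.affine)
    nib.save(img, str(path))


def save_mask(mask: BinaryMask, affine: np.ndarray, path) -> None:
    """Write a binary mask as uint8 NIfTI-1."""
    img = nib.Nifti1Image(mask.data.astype(np.uint8), np.asarray(affine, dtype=float))
    nib.save(img, str(path))
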