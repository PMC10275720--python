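"""Spatial data model and NIfTI I/O shared by every pipeline stage.

All volumes live on a regular 3-D grid with a 4x4 affine mapping 0-based
voxel indices to world coordinates in millimetres (NIfTI voxel-to-world
convention). Time series add a fourth axis and a repetition time in seconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage


class FormatError(ValueError):
    """Raised for unreadable or structurally invalid image files."""


@dataclass
class ImageVolume:
    """A 3-D scalar grid plus voxel-to-world affine.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values (unitless unless stated by the producer).
    affine : ndarray, shape (4, 4)
        Homogeneous voxel-index -> world-mm transform; must be invertible.
    space : str
        Free-text identifier of the coordinate frame.
    """

    data: np.ndarray
    affine: np.ndarray
    space: str = "synthetic"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"expected a non-empty 3-D grid, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the linear part)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, point) -> np.ndarray:
        return voxel_world_transform(self, point, "voxel_to_world")

    def world_to_voxel(self, point) -> np.ndarray:
        return voxel_world_transform(self, point, "world_to_voxel")

    def is_binary(self) -> bool:
        return bool(np.isin(self.data, (0, 1)).all())


@dataclass
class TimeSeriesImage:
    """A 4-D BOLD grid (x, y, z, t) with repetition time ``tr`` in seconds."""

    data: np.ndarray
    affine: np.ndarray
    tr: float
    space: str = "synthetic"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4 or self.data.shape[3] < 2:
            raise ValueError("time series needs 4 dimensions and >= 2 volumes")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def frame(self, t: int) -> ImageVolume:
        return ImageVolume(self.data[..., t], self.affine, self.space)


def voxel_world_transform(volume, point, direction: str) -> np.ndarray:
    """Map a 3-vector between voxel-index and world-mm coordinates.

    ``direction`` is ``"voxel_to_world"`` (apply the affine) or
    ``"world_to_voxel"`` (apply its inverse); composing both is the identity.
    """
    point = np.asarray(point, dtype=float)
    if point.shape[-1] != 3:
        raise ValueError("point must be a 3-vector (or array of them)")
    aff = volume.affine
    if direction == "world_to_voxel":
        aff = np.linalg.inv(aff)
    elif direction != "voxel_to_world":
        raise ValueError(f"unknown direction {direction!r}")
    return point @ aff[:3, :3].T + aff[:3, 3]


def save_nifti(path, volume) -> None:
    """Write an ImageVolume or TimeSeriesImage as NIfTI-1 (.nii / .nii.gz)."""
    img = nib.Nifti1Image(np.asarray(volume.data), volume.affine)
    if isinstance(volume, TimeSeriesImage):
        zooms = list(img.header.get_zooms()[:3]) + [volume.tr]
        img.header.set_zooms(zooms)
        img.header.set_xyzt_units(xyz="mm", t="sec")
    else:
        img.header.set_xyzt_units(xyz="mm")
    nib.save(img, str(path))


def load_nifti(path, space: str = "unknown"):
    """Read a NIfTI file; returns ImageVolume (3-D) or TimeSeriesImage (4-D).

    The repetition time of a 4-D series is recovered from the header's
    time-axis spacing (pixdim[4]).
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    affine = img.affine
    if data.ndim == 3:
        return ImageVolume(data, affine, space)
    if data.ndim == 4:
        tr = float(img.header.get_zooms()[3])
        return TimeSeriesImage(data, affine, tr, space)
    raise FormatError(f"unsupported NIfTI dimensionality {data.ndim} in {path}")


def resample_to_grid(source: ImageVolume, target_affine, target_shape,
                     method: str = "linear") -> ImageVolume:
    """Resample ``source`` onto the grid (``target_affine``, ``target_shape``).

    ``method`` is ``"nearest"`` (order 0; required for binary masks so the
    value set is preserved) or ``"linear"`` (order 1). Voxels falling outside
    the source footprint fill with 0, keeping masks binary.
    """
    if method not in ("nearest", "linear"):
        raise ValueError(f"unknown method {method!r}")
    target_affine = np.asarray(target_affine, dtype=float)
    target_shape = tuple(int(n) for n in target_shape)
    # target voxel index -> source voxel index
    xform = np.linalg.inv(source.affine) @ target_affine
    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in target_shape), indexing="ij")
    idx = np.stack([ii, jj, kk], axis=0).reshape(3, -1)
    src = (xform[:3, :3] @ idx) + xform[:3, 3:4]
    inside = ((src >= -0.5) & (src <= np.array(source.shape)[:, None] - 0.5)).all(axis=0)
    if not inside.any():
        warnings.warn("target grid does not overlap the source footprint; "
                      "output is zero-filled", stacklevel=2)
    order = 0 if method == "nearest" else 1
    out = ndimage.map_coordinates(source.data.astype(float), src, order=order,
                                  mode="constant", cval=0.0)
    out = out.reshape(target_shape)
    if method == "nearest":
        out = out.astype(source.data.dtype)
    return ImageVolume(out, target_affine, source.space)


_COORD_CACHE: dict = {}


def grid_world_coordinates(affine, shape) -> np.ndarray:
    """World-mm coordinates of every voxel centre, shape (nx, ny, nz, 3).

    Cached per grid (read-only result) — every stage queries the same grid
    repeatedly.
    """
    affine = np.asarray(affine, dtype=float)
    key = (affine.tobytes(), tuple(int(n) for n in shape))
    hit = _COORD_CACHE.get(key)
    if hit is not None:
        return hit
    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    idx = np.stack([ii, jj, kk], axis=-1).astype(float)
    out = idx @ affine[:3, :3].T + affine[:3, 3]
    out.setflags(write=False)
    if len(_COORD_CACHE) > 8:
        _COORD_CACHE.clear()
    _COORD_CACHE[key] = out
    return out


def centered_grid(shape, spacing) -> np.ndarray:
    """Affine for a grid of ``shape`` at isotropic ``spacing`` mm whose world
    origin sits on the centre voxel (so the mid-sagittal plane x = 0 is a
    voxel column — left/right mirror symmetry is exact)."""
    shape = np.asarray(shape, int)
    aff = np.eye(4)
    aff[:3, :3] *= float(spacing)
    aff[:3, 3] = -(shape // 2) * float(spacing)
    return aff
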