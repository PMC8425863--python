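"""Voxel containers and displacement-field numerics.

All volumes are axis-aligned. Arrays are indexed ``(i, j, k)`` along the
world x/y/z axes; the world coordinate of voxel ``(i, j, k)`` is
``origin + (i, j, k) * spacing`` (voxel centers, mm).

Displacement fields follow one convention throughout the package: a
:class:`VectorField` lives on the *fixed* (daily) lattice and maps a
fixed-frame point ``x`` to the moving-frame (planning CT) point
``x + u(x)``.  Warping an image by such a field is therefore a pull-back,
and dose mapping back onto the planning CT uses the numerical inverse
(:func:`invert_dvf`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterator, Tuple

import numpy as np
import SimpleITK as sitk
from scipy.ndimage import map_coordinates

__all__ = [
    "ImageGrid",
    "VectorField",
    "StructureSet",
    "warp_image",
    "warp_mask",
    "invert_dvf",
    "jacobian_determinant",
    "read_image",
    "write_image",
    "read_dvf",
    "write_dvf",
]


@dataclass
class ImageGrid:
    """A 3D scalar volume (HU or Gy) with its lattice geometry."""

    data: np.ndarray            # shape (nx, ny, nz)
    spacing: np.ndarray         # (3,) mm
    origin: np.ndarray          # (3,) mm, world coordinate of voxel (0,0,0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got shape {self.data.shape}")
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_lattice(self, other: "ImageGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape (nx, ny, nz, 3)."""
        axes = [self.origin[d] + np.arange(self.shape[d]) * self.spacing[d] for d in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous voxel indices for world points (..., 3)."""
        return (np.asarray(points, dtype=float) - self.origin) / self.spacing

    def like(self, data: np.ndarray) -> "ImageGrid":
        """A new grid on this lattice with different voxel values."""
        if data.shape[:3] != self.shape:
            raise ValueError(f"shape {data.shape} incompatible with lattice {self.shape}")
        return ImageGrid(data, self.spacing.copy(), self.origin.copy())

    def copy(self) -> "ImageGrid":
        return ImageGrid(self.data.copy(), self.spacing.copy(), self.origin.copy())

    # --- SimpleITK bridge (sitk arrays are indexed z,y,x) ---

    def to_sitk(self, dtype=np.float32) -> sitk.Image:
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.data.astype(dtype).transpose(2, 1, 0)))
        img.SetSpacing(tuple(float(s) for s in self.spacing))
        img.SetOrigin(tuple(float(o) for o in self.origin))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "ImageGrid":
        arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        return cls(arr, np.array(img.GetSpacing()), np.array(img.GetOrigin()))


@dataclass
class VectorField:
    """Per-voxel 3D displacement (mm) on an :class:`ImageGrid` lattice.

    ``convention`` records the mapping direction; the package default is
    ``"fixed-to-moving"``: defined on the daily grid, pointing into pCT space.
    """

    data: np.ndarray            # shape (nx, ny, nz, 3), mm
    spacing: np.ndarray
    origin: np.ndarray
    convention: str = "fixed-to-moving"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.data.ndim != 4 or self.data.shape[-1] != 3:
            raise ValueError(f"expected (nx,ny,nz,3) displacement array, got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("displacement field contains non-finite values")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def grid(self) -> ImageGrid:
        """The lattice, as an (empty) ImageGrid description."""
        return ImageGrid(np.zeros(self.shape, dtype=np.uint8), self.spacing.copy(), self.origin.copy())

    def max_magnitude(self) -> float:
        return float(np.sqrt((self.data ** 2).sum(axis=-1)).max())

    def sample(self, points: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Linearly interpolate the displacement at world points (..., 3)."""
        pts = np.asarray(points, dtype=float)
        idx = (pts - self.origin) / self.spacing
        flat = idx.reshape(-1, 3).T
        out = np.empty((flat.shape[1], 3))
        for c in range(3):
            out[:, c] = map_coordinates(self.data[..., c], flat, order=1, mode="constant", cval=fill)
        return out.reshape(pts.shape)


@dataclass
class StructureSet:
    """Named binary masks sharing one reference lattice."""

    masks: Dict[str, np.ndarray]
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError(f"masks on inconsistent lattices: {shapes}")
        self.masks = {k: np.asarray(v, dtype=bool) for k, v in self.masks.items()}

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def __iter__(self) -> Iterator[str]:
        return iter(self.masks)

    def names(self):
        return list(self.masks)

    def volume_cc(self, name: str) -> float:
        return float(self.masks[name].sum() * np.prod(self.spacing) / 1000.0)


# ---------------------------------------------------------------------------
# Field numerics
# ---------------------------------------------------------------------------

def warp_image(
    moving: ImageGrid,
    dvf: VectorField,
    interpolation: str = "linear",
) -> Tuple[ImageGrid, np.ndarray]:
    """Pull ``moving`` back through ``dvf``: output(x) = moving(x + u(x)).

    The output lives on the dvf's lattice.  Returns ``(warped, valid)``
    where ``valid`` flags voxels whose sample point fell inside the moving
    volume; out-of-bounds voxels hold 0 and are flagged invalid, never
    extrapolated.
    """
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    order = 1 if interpolation == "linear" else 0
    target = dvf.grid
    pts = target.voxel_centers() + dvf.data      # world sample points in moving frame
    idx = moving.world_to_index(pts)
    flat = idx.reshape(-1, 3).T
    vals = map_coordinates(moving.data.astype(float), flat, order=order, mode="constant", cval=0.0)
    eps = 1e-9
    hi = np.array(moving.shape) - 1
    valid = np.all((flat.T >= -eps) & (flat.T <= hi + eps), axis=1)
    out = vals.reshape(target.shape)
    out[~valid.reshape(target.shape)] = 0.0
    return target.like(out), valid.reshape(target.shape)


def warp_mask(mask: np.ndarray, grid: ImageGrid, dvf: VectorField) -> np.ndarray:
    """Warp a binary mask (on ``grid``) onto the dvf lattice.

    Linear interpolation of the indicator thresholded at 0.5 — slightly
    smoother boundaries than nearest-neighbour under subvoxel motion.
    """
    warped, valid = warp_image(grid.like(mask.astype(float)), dvf, interpolation="linear")
    return (warped.data >= 0.5) & valid


def invert_dvf(
    dvf: VectorField,
    tol_mm: float = 0.01,
    max_iter: int = 50,
    target: ImageGrid | None = None,
) -> Tuple[VectorField, np.ndarray]:
    """Numerically invert a displacement field by fixed-point iteration.

    Solves v(y) = -u(y + v(y)) on the ``target`` lattice (default: the
    field's own lattice).  Returns ``(inverse, reliable)`` where
    ``reliable`` marks voxels whose composition residual
    ``‖u(y + v(y)) + v(y)‖`` ended below ``10 * tol_mm`` and whose iterates
    stayed inside the field's domain.
    """
    grid = target if target is not None else dvf.grid
    y = grid.voxel_centers()
    v = np.zeros(grid.shape + (3,))
    lo = dvf.origin
    hi = dvf.origin + (np.array(dvf.shape) - 1) * dvf.spacing
    for _ in range(max_iter):
        u_at = dvf.sample(y + v, fill=np.nan)
        new_v = -u_at
        bad = ~np.isfinite(new_v).all(axis=-1)
        new_v[bad] = v[bad]
        step = np.sqrt(((new_v - v) ** 2).sum(axis=-1))
        v = new_v
        if np.nanmax(step) < tol_mm:
            break
    u_at = dvf.sample(y + v, fill=np.nan)
    resid = np.sqrt(((u_at + v) ** 2).sum(axis=-1))
    inside = np.all((y + v >= lo) & (y + v <= hi), axis=-1)
    reliable = inside & np.isfinite(resid) & (resid <= 10 * tol_mm)
    v[~np.isfinite(v).all(axis=-1)] = 0.0
    return VectorField(v, grid.spacing.copy(), grid.origin.copy(), convention="moving-to-fixed"), reliable


def jacobian_determinant(dvf: VectorField) -> np.ndarray:
    """Voxelwise Jacobian determinant of the map x ↦ x + u(x)."""
    jac = np.empty(dvf.shape + (3, 3))
    for c in range(3):
        grads = np.gradient(dvf.data[..., c], *dvf.spacing)
        for d in range(3):
            jac[..., c, d] = grads[d]
        jac[..., c, c] += 1.0
    return np.linalg.det(jac)


# ---------------------------------------------------------------------------
# I/O — NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) through SimpleITK
# ---------------------------------------------------------------------------

def write_image(grid: ImageGrid, path: str | Path) -> None:
    sitk.WriteImage(grid.to_sitk(), str(path))


def read_image(path: str | Path) -> ImageGrid:
    return ImageGrid.from_sitk(sitk.ReadImage(str(path)))


def write_dvf(dvf: VectorField, path: str | Path) -> None:
    """Write a 3-component vector image plus a JSON sidecar with the convention."""
    arr = np.ascontiguousarray(dvf.data.astype(np.float64).transpose(2, 1, 0, 3))
    img = sitk.GetImageFromArray(arr, isVector=True)
    img.SetSpacing(tuple(float(s) for s in dvf.spacing))
    img.SetOrigin(tuple(float(o) for o in dvf.origin))
    sitk.WriteImage(img, str(path))
    sidecar = Path(str(path) + ".json")
    sidecar.write_text(json.dumps({"convention": dvf.convention, "units": "mm"}))


def read_dvf(path: str | Path) -> VectorField:
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0, 3)
    convention = "fixed-to-moving"
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        convention = json.loads(sidecar.read_text()).get("convention", convention)
    return VectorField(arr, np.array(img.GetSpacing()), np.array(img.GetOrigin()), convention=convention)
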