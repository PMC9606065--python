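"""Volumetric grids and NIfTI I/O.

All volumes in this package live on a :class:`VolumeGrid`: a 3D scalar array
plus voxel spacing and origin. The array axis convention is ``(z, y, x)`` —
axis 0 indexes axial slices, axes 1 and 2 the in-plane rows and columns.
Spacing and origin follow the same ``(z, y, x)`` order, in millimetres.

NIfTI files store data in ``(x, y, z)`` order; the reader/writer transposes
so that in-memory arrays are always axial-first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["VolumeGrid", "read_volume", "write_volume"]


@dataclass
class VolumeGrid:
    """A 3D scalar field with geometry.

    Parameters
    ----------
    values : ndarray, shape (nz, ny, nx)
        Voxel values. Unit depends on use: SUV, HU, counts, or integer label.
    spacing : tuple of float
        Voxel edge lengths ``(dz, dy, dx)`` in mm; all positive.
    origin : tuple of float
        World coordinate of voxel ``(0, 0, 0)`` in mm, ``(z, y, x)`` order.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (3.0, 3.3, 3.3)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    is_label: bool = field(default=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must be length-3")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacing components must be > 0, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        if self.is_label:
            if not np.issubdtype(self.values.dtype, np.integer):
                raise ValueError("label volume must have integer dtype")
            if self.values.min(initial=0) < 0:
                raise ValueError("label volume contains negative labels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def n_slices(self) -> int:
        return self.values.shape[0]

    @property
    def voxel_volume_ml(self) -> float:
        """Voxel volume in millilitres (1 ml = 1000 mm^3)."""
        dz, dy, dx = self.spacing
        return dz * dy * dx / 1000.0

    def same_geometry(self, other: "VolumeGrid", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def require_same_geometry(self, other: "VolumeGrid", what: str = "volumes") -> None:
        if not self.same_geometry(other):
            raise ValueError(
                f"{what} are not on the same grid: "
                f"{self.shape}/{self.spacing} vs {other.shape}/{other.spacing}"
            )

    def with_values(self, values: np.ndarray, is_label: bool | None = None) -> "VolumeGrid":
        """New grid sharing this geometry with different voxel values."""
        return VolumeGrid(
            values,
            spacing=self.spacing,
            origin=self.origin,
            is_label=self.is_label if is_label is None else is_label,
        )

    def copy(self) -> "VolumeGrid":
        return self.with_values(self.values.copy())


def _affine(grid: VolumeGrid) -> np.ndarray:
    """NIfTI affine for a grid (data written in (x, y, z) order)."""
    dz, dy, dx = grid.spacing
    oz, oy, ox = grid.origin
    aff = np.diag([dx, dy, dz, 1.0])
    aff[:3, 3] = [ox, oy, oz]
    return aff


def write_volume(grid: VolumeGrid, path: str) -> None:
    """Write a grid as NIfTI-1 (.nii or .nii.gz).

    Float volumes are stored as float32; label volumes keep an integer dtype.
    """
    if grid.is_label:
        data = np.asarray(grid.values, dtype=np.int32)
    else:
        data = np.asarray(grid.values, dtype=np.float32)
    img = nib.Nifti1Image(np.transpose(data, (2, 1, 0)), _affine(grid))
    img.header.set_zooms((grid.spacing[2], grid.spacing[1], grid.spacing[0]))
    nib.save(img, path)


def read_volume(path: str, is_label: bool = False) -> VolumeGrid:
    """Read a NIfTI-1 volume into axial-first (z, y, x) order.

    Spacing is taken from the header zooms; the origin from the affine
    translation. Raises ``ValueError`` naming the offending header field
    when geometry is unusable.
    """
    img = nib.load(path)
    if img.ndim != 3:
        raise ValueError(f"{path}: expected 3D NIfTI, got shape {img.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError(f"{path}: invalid header field 'pixdim' (zooms={zooms})")
    data = np.transpose(np.asanyarray(img.dataobj), (2, 1, 0))
    if is_label:
        data = np.asarray(np.rint(data), dtype=np.int32)
    else:
        data = np.asarray(data, dtype=np.float32)
    origin = img.affine[:3, 3]
    return VolumeGrid(
        data,
        spacing=(float(zooms[2]), float(zooms[1]), float(zooms[0])),
        origin=(float(origin[2]), float(origin[1]), float(origin[0])),
        is_label=is_label,
    )
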