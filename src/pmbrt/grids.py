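"""Voxel-grid data model, file I/O and geometry utilities.

Conventions used throughout the package:

* arrays are indexed ``[x, y, z]`` with ``z`` the beam-depth axis in
  generated fields;
* voxel indices are 0-based and positions refer to voxel centres;
* all physical lengths are millimetres;
* dose is stored as percent of the prescribed dose (``D_50`` = 100%),
  LET in keV/um.

Two grids are *congruent* when shapes, spacings and origins agree within
``CONGRUENCE_TOL_MM``.  Metrics never resample: operating on non-congruent
grids is an explicit error.
"""

from __future__ import annotations

import dataclasses
import enum
from pathlib import Path

import numpy as np
import SimpleITK as sitk

CONGRUENCE_TOL_MM = 1e-6


class GridError(ValueError):
    """Invalid grid data or metadata."""


class FormatError(GridError):
    """File cannot be interpreted as a supported voxel-grid format."""


class DimensionalityError(GridError):
    """Data is not a 3D scalar field."""


class CongruenceError(GridError):
    """Grids/masks do not share shape, spacing and origin."""


class Quantity(str, enum.Enum):
    DOSE = "dose"
    LET = "let"
    RBE = "rbe"
    RBE_WEIGHTED_DOSE = "rbe_weighted_dose"
    GAMMA = "gamma"


# quantities that must be finite and non-negative everywhere; gamma grids may
# carry NaN for voxels below the evaluation cutoff
_NONNEG_QUANTITIES = frozenset(
    {Quantity.DOSE, Quantity.LET, Quantity.RBE, Quantity.RBE_WEIGHTED_DOSE}
)


@dataclasses.dataclass
class VoxelGrid:
    """3D scalar field with spacing/origin metadata.

    Parameters
    ----------
    values
        3D array, axis order (x, y, z).
    spacing
        Voxel spacing per axis in mm, strictly positive.
    origin
        Position of voxel (0, 0, 0) centre in mm.
    quantity
        Physical quantity stored in the grid.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    quantity: Quantity = Quantity.DOSE

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise DimensionalityError(
                f"expected 3D scalar data, got {self.values.ndim}D"
            )
        self.quantity = Quantity(self.quantity)
        self.spacing = tuple(float(s) for s in np.asarray(self.spacing).ravel())
        self.origin = tuple(float(o) for o in np.asarray(self.origin).ravel())
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise GridError("spacing and origin must have 3 components")
        if any(s <= 0 for s in self.spacing):
            raise GridError(f"spacing must be strictly positive, got {self.spacing}")
        if self.quantity in _NONNEG_QUANTITIES:
            if not np.all(np.isfinite(self.values)):
                raise GridError("grid values must be finite")
            if float(self.values.min()) < 0:
                raise GridError(
                    f"{self.quantity.value} values must be non-negative"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def positions(self, axis: int) -> np.ndarray:
        """Voxel-centre coordinates (mm) along one axis."""
        n = self.values.shape[axis]
        return self.origin[axis] + np.arange(n) * self.spacing[axis]

    def is_congruent(self, other: "VoxelGrid | StructureMask",
                     tol: float = CONGRUENCE_TOL_MM) -> bool:
        other_shape = other.mask.shape if isinstance(other, StructureMask) else other.values.shape
        return (
            self.values.shape == other_shape
            and np.allclose(self.spacing, other.spacing, rtol=0, atol=tol)
            and np.allclose(self.origin, other.origin, rtol=0, atol=tol)
        )

    def with_values(self, values: np.ndarray,
                    quantity: Quantity | None = None) -> "VoxelGrid":
        return VoxelGrid(values, self.spacing, self.origin,
                         quantity or self.quantity)


@dataclasses.dataclass
class StructureMask:
    """Named binary structure (PTV, OAR, ...) congruent with a VoxelGrid."""

    name: str
    mask: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise DimensionalityError("mask must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def require_congruent(grid: VoxelGrid, other: "VoxelGrid | StructureMask") -> None:
    if not grid.is_congruent(other):
        name = getattr(other, "name", "grid")
        raise CongruenceError(
            f"{name!r} is not congruent with the evaluated grid "
            "(shape/spacing/origin mismatch); resampling is not supported"
        )


def require_nonempty(mask: StructureMask) -> None:
    if mask.n_voxels == 0:
        raise GridError(f"structure {mask.name!r} is empty")


@dataclasses.dataclass
class Profile:
    """1D sampled curve: voxel-centre positions (mm) and values."""

    positions: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape or self.positions.ndim != 1:
            raise GridError("profile positions/values must be matching 1D arrays")

    def __len__(self) -> int:
        return self.values.size


# ---------------------------------------------------------------------------
# file I/O (NRRD / MetaImage via SimpleITK; lossless for 32-bit scalars)
# ---------------------------------------------------------------------------

_FORMAT_EXT = {"nrrd": (".nrrd",), "metaimage": (".mhd", ".mha")}


def _check_format(path: Path, format: str | None) -> str:
    ext = path.suffix.lower()
    if format is None:
        for fmt, exts in _FORMAT_EXT.items():
            if ext in exts:
                return fmt
        raise FormatError(f"cannot infer grid format from extension {ext!r}")
    if format not in _FORMAT_EXT:
        raise FormatError(f"unsupported format {format!r}")
    if ext not in _FORMAT_EXT[format]:
        raise FormatError(f"extension {ext!r} does not match format {format!r}")
    return format


def write_grid(grid: VoxelGrid, path: str | Path, format: str | None = None) -> None:
    """Write a grid as NRRD or MetaImage (32-bit float, uncompressed).

    Refuses non-finite values.  Output is byte-deterministic for repeated
    writes of the same grid.
    """
    path = Path(path)
    _check_format(path, format)
    if not np.all(np.isfinite(grid.values)):
        raise GridError("refusing to write non-finite grid values")
    arr = np.ascontiguousarray(grid.values.T.astype(np.float32))  # (z, y, x)
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(grid.spacing)
    img.SetOrigin(grid.origin)
    sitk.WriteImage(img, str(path), useCompression=False)


def read_grid(path: str | Path, format: str | None = None,
              quantity: Quantity = Quantity.DOSE) -> VoxelGrid:
    """Read a 3D scalar grid; round-trips bit-exactly with :func:`write_grid`."""
    path = Path(path)
    _check_format(path, format)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # pragma: no cover - ITK error text varies
        raise FormatError(f"cannot read {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise DimensionalityError(
            f"{path} holds {img.GetDimension()}D data, expected 3D"
        )
    values = sitk.GetArrayFromImage(img).T  # (x, y, z)
    return VoxelGrid(values, img.GetSpacing(), img.GetOrigin(), quantity)


def write_mask(mask: StructureMask, path: str | Path,
               format: str | None = None) -> None:
    """Write a binary mask as an 8-bit NRRD/MetaImage volume."""
    path = Path(path)
    _check_format(path, format)
    img = sitk.GetImageFromArray(np.ascontiguousarray(mask.mask.T.astype(np.uint8)))
    img.SetSpacing(mask.spacing)
    img.SetOrigin(mask.origin)
    sitk.WriteImage(img, str(path), useCompression=False)


def read_mask(path: str | Path, name: str | None = None,
              format: str | None = None) -> StructureMask:
    path = Path(path)
    _check_format(path, format)
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise DimensionalityError(
            f"{path} holds {img.GetDimension()}D data, expected 3D"
        )
    values = sitk.GetArrayFromImage(img).T
    return StructureMask(name or path.stem, values > 0,
                         img.GetSpacing(), img.GetOrigin())


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def extract_profile(grid: VoxelGrid, axis: int, index: tuple[int, int]) -> Profile:
    """Extract the lattice line along ``axis`` at the given coordinates.

    ``index`` holds the voxel indices of the two remaining axes, in
    ascending axis order.  Values are copied untouched; positions are the
    voxel-centre coordinates along ``axis``.
    """
    if axis not in (0, 1, 2):
        raise GridError(f"axis must be 0, 1 or 2, got {axis}")
    others = [a for a in range(3) if a != axis]
    if len(index) != 2:
        raise GridError("index must give lattice coordinates for the two fixed axes")
    slicer: list[object] = [slice(None)] * 3
    for a, i in zip(others, index):
        i = int(i)
        if not 0 <= i < grid.values.shape[a]:
            raise IndexError(
                f"index {i} out of bounds for axis {a} "
                f"(size {grid.values.shape[a]})"
            )
        slicer[a] = i
    return Profile(grid.positions(axis), grid.values[tuple(slicer)].copy())


def depth_to_index(grid: VoxelGrid, depth_mm: float, axis: int = 2) -> int:
    """Nearest lattice index along ``axis`` for a physical position (mm)."""
    k = int(round((depth_mm - grid.origin[axis]) / grid.spacing[axis]))
    if not 0 <= k < grid.values.shape[axis]:
        raise IndexError(
            f"position {depth_mm} mm is outside the grid along axis {axis}"
        )
    return k


def build_box_mask(grid: VoxelGrid, name: str,
                   lower: tuple[float, float, float],
                   upper: tuple[float, float, float]) -> StructureMask:
    """Axis-aligned box mask: voxels whose centres lie in [lower, upper] mm."""
    sel = np.ones(grid.values.shape, dtype=bool)
    for axis in range(3):
        pos = grid.positions(axis)
        keep = (pos >= lower[axis]) & (pos <= upper[axis])
        shape = [1, 1, 1]
        shape[axis] = pos.size
        sel &= keep.reshape(shape)
    return StructureMask(name, sel, grid.spacing, grid.origin)
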