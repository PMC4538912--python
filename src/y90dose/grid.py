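"""Voxel-grid data model, volume I/O, and CT-to-density/material mapping.

All stages of the pipeline operate on co-registered 3D scalar volumes on one
grid: activity (Bq), counts, disintegrations, density (g/cc), material
labels, and dose (Gy).  The index convention is 0-based ``(i, j, k)`` with
the world position of a voxel center at ``origin + index * spacing`` (mm).

Standard-format I/O (NIfTI and MetaImage) is delegated to SimpleITK; arrays
are transposed between SimpleITK's ``(z, y, x)`` layout and this package's
``(i, j, k) == (x, y, z)`` convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import SimpleITK as sitk

__all__ = [
    "VoxelGrid",
    "MaterialMap",
    "MATERIALS",
    "MaterialThresholds",
    "DensityLUT",
    "default_density_lut",
    "read_volume",
    "write_volume",
    "hu_to_density",
    "density_to_material",
    "load_calibration_config",
]

_SUPPORTED_SUFFIXES = (".nii", ".nii.gz", ".mha", ".mhd")


@dataclass
class VoxelGrid:
    """A 3D scalar volume on a regular grid.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        One scalar per voxel, indexed ``(i, j, k)``.
    spacing : tuple of float
        Voxel spacing per axis in mm.
    origin : tuple of float
        World coordinate (mm) of the center of voxel ``(0, 0, 0)``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("not a 3D volume")
        if any(d <= 0 for d in self.values.shape):
            raise ValueError("all grid dimensions must be positive")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive values (mm)")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_cc(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    @property
    def is_isotropic(self) -> bool:
        s = self.spacing
        return abs(s[0] - s[1]) < 1e-9 and abs(s[1] - s[2]) < 1e-9

    def require_isotropic(self) -> float:
        """Return the isotropic spacing, or raise for anisotropic grids."""
        if not self.is_isotropic:
            raise ValueError(
                "kernel-based engines require isotropic voxel spacing; "
                f"got {self.spacing}"
            )
        return self.spacing[0]

    def with_values(self, values: np.ndarray) -> "VoxelGrid":
        """A new grid with identical geometry and different values."""
        if np.shape(values) != self.dims:
            raise ValueError("values shape must match grid dims")
        return replace(self, values=np.asarray(values))

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along one axis."""
        n = self.dims[axis]
        return self.origin[axis] + np.arange(n) * self.spacing[axis]

    def total(self) -> float:
        return float(self.values.sum())


#: Material labels, in order of increasing density range.
MATERIALS = ("air", "lung", "soft_tissue", "bone")


@dataclass
class MaterialMap:
    """Per-voxel material labels (codes indexing into :data:`MATERIALS`)."""

    grid: VoxelGrid
    labels: tuple[str, ...] = MATERIALS

    def label_of(self, index: tuple[int, int, int]) -> str:
        return self.labels[int(self.grid.values[index])]


@dataclass(frozen=True)
class MaterialThresholds:
    """Density cut-points (g/cc) of the four contiguous material ranges.

    ``air < air_lung <= lung < lung_soft <= soft_tissue < soft_bone <= bone``.
    The half-open ranges cover [0, inf), so the mapping is total.
    """

    air_lung: float = 0.05
    lung_soft: float = 0.70
    soft_bone: float = 1.50

    def __post_init__(self) -> None:
        if not (0.0 < self.air_lung < self.lung_soft < self.soft_bone):
            raise ValueError(
                "material thresholds must be strictly increasing and positive"
            )

    @property
    def edges(self) -> tuple[float, float, float]:
        return (self.air_lung, self.lung_soft, self.soft_bone)


@dataclass
class DensityLUT:
    """Piecewise-linear CT-number -> density (g/cc) lookup table."""

    knots: Sequence[tuple[float, float]]

    def __post_init__(self) -> None:
        if len(self.knots) == 0:
            raise ValueError("density LUT must have at least one knot")
        knots = sorted((float(h), float(d)) for h, d in self.knots)
        hu = np.array([k[0] for k in knots])
        rho = np.array([k[1] for k in knots])
        if np.any(np.diff(hu) <= 0):
            raise ValueError("CT-number knots must be strictly increasing")
        if np.any(rho < 0):
            raise ValueError("densities must be non-negative")
        self.knots = tuple(knots)
        self._hu = hu
        self._rho = rho

    def __call__(self, ct: np.ndarray) -> np.ndarray:
        """Interpolate densities; CT values outside the table are clamped."""
        return np.interp(np.asarray(ct, dtype=float), self._hu, self._rho)


def default_density_lut() -> DensityLUT:
    """Two-segment generic CT calibration (scanner LUTs vary; configurable)."""
    return DensityLUT([(-1000.0, 0.001), (0.0, 1.000), (3000.0, 2.90)])


def read_volume(path: str | Path, format: str | None = None) -> VoxelGrid:
    """Read a 3D volume from NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd).

    Dims, spacing, and origin are taken from the header; the value array is
    returned in this package's ``(i, j, k)`` index convention.  A warning is
    emitted for anisotropic spacing (kernel-based engines will refuse such
    grids).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    name = path.name.lower()
    if format is None and not name.endswith(_SUPPORTED_SUFFIXES):
        raise ValueError(
            f"unsupported format {path.suffix!r}; expected one of "
            f"{_SUPPORTED_SUFFIXES}"
        )
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise ValueError("not a 3D volume")
    values = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    grid = VoxelGrid(
        values=values, spacing=tuple(img.GetSpacing()), origin=tuple(img.GetOrigin())
    )
    if not grid.is_isotropic:
        warnings.warn(
            f"volume {path.name} has anisotropic spacing {grid.spacing}; "
            "kernel-based dose engines will refuse this grid",
            stacklevel=2,
        )
    return grid


def write_volume(grid: VoxelGrid, path: str | Path, dtype=np.float32) -> Path:
    """Write a grid to NIfTI or MetaImage (float32 volumes, uint8 masks)."""
    path = Path(path)
    if not path.name.lower().endswith(_SUPPORTED_SUFFIXES):
        raise ValueError(
            f"unsupported format {path.suffix!r}; expected one of "
            f"{_SUPPORTED_SUFFIXES}"
        )
    arr = np.ascontiguousarray(grid.values.astype(dtype).transpose(2, 1, 0))
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(grid.spacing)
    img.SetOrigin(grid.origin)
    sitk.WriteImage(img, str(path))
    return path


def hu_to_density(ct: VoxelGrid, lut: DensityLUT | None = None) -> VoxelGrid:
    """Map CT numbers to mass density (g/cc) through a piecewise-linear LUT."""
    if lut is None:
        lut = default_density_lut()
    return ct.with_values(lut(ct.values))


def load_calibration_config(
    path: str | Path,
) -> tuple[MaterialThresholds, DensityLUT]:
    """Read material thresholds and density LUT from a YAML/JSON config.

    Expected sections (both optional; defaults fill the gaps)::

        materials:
          air_lung: 0.05
          lung_soft: 0.70
          soft_bone: 1.50
        density_lut:
          - [-1000, 0.001]
          - [0, 1.0]
          - [3000, 2.90]
    """
    import yaml

    cfg = yaml.safe_load(Path(path).read_text()) or {}
    thresholds = MaterialThresholds(**cfg.get("materials", {}))
    if "density_lut" in cfg:
        lut = DensityLUT([tuple(knot) for knot in cfg["density_lut"]])
    else:
        lut = default_density_lut()
    return thresholds, lut


def density_to_material(
    rho: VoxelGrid, thresholds: MaterialThresholds | None = None
) -> MaterialMap:
    """Label every voxel as air, lung, soft tissue, or bone by density range."""
    if thresholds is None:
        thresholds = MaterialThresholds()
    values = np.asarray(rho.values, dtype=float)
    if np.any(~np.isfinite(values)) or np.any(values < 0):
        raise ValueError("densities must be finite and non-negative")
    codes = np.digitize(values, thresholds.edges).astype(np.uint8)
    return MaterialMap(grid=rho.with_values(codes))
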