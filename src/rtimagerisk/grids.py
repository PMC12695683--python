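"""Dose grids, structure sets and voxel masks.

Geometry lives in the DICOM patient coordinate system, in millimetres.
Arrays are indexed ``(z, y, x)``; ``origin`` is the centre of voxel
``[0, 0, 0]`` given as ``(x, y, z)`` and ``spacing`` as ``(dx, dy, dz)``,
matching DICOM's ImagePositionPatient / PixelSpacing conventions. Only
axis-aligned grids (identity direction cosines) are supported; that is what
every RTDOSE this pipeline consumes or produces uses.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .errors import GridMismatchError, ParameterError

IDENTITY_ORIENTATION = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0)


@dataclass
class DoseGrid:
    """A 3-D scalar dose distribution with physical geometry.

    Parameters
    ----------
    origin : (3,) float
        Patient-coordinate position (x, y, z) in mm of the centre of voxel
        ``values[0, 0, 0]``.
    spacing : (3,) float
        Voxel size (dx, dy, dz) in mm; all strictly positive.
    values : (nz, ny, nx) float array
        Dose per voxel in Gy; finite and non-negative.
    orientation : 6-tuple
        Direction cosines of rows and columns (DICOM ImageOrientationPatient).
    frame_ref : str
        Frame-of-reference UID the geometry refers to.
    """

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray
    orientation: tuple = IDENTITY_ORIENTATION
    frame_ref: str = ""

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.origin.shape != (3,) or self.spacing.shape != (3,):
            raise ParameterError("origin and spacing must be length-3 vectors")
        if self.values.ndim != 3:
            raise ParameterError("values must be a 3-D array indexed (z, y, x)")
        if not np.all(self.spacing > 0):
            raise ParameterError("all spacings must be strictly positive")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("dose values must be finite")
        if np.any(self.values < 0):
            raise ParameterError("dose values must be non-negative")
        if not np.allclose(self.orientation, IDENTITY_ORIENTATION, atol=1e-6):
            raise ParameterError(
                "only axis-aligned grids (identity direction cosines) are supported"
            )

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axis_centers(self):
        """Voxel-centre coordinates per axis, returned as (x, y, z) arrays."""
        nz, ny, nx = self.values.shape
        x = self.origin[0] + self.spacing[0] * np.arange(nx)
        y = self.origin[1] + self.spacing[1] * np.arange(ny)
        z = self.origin[2] + self.spacing[2] * np.arange(nz)
        return x, y, z

    def same_lattice(self, other: "DoseGrid", tol: float = 1e-6) -> bool:
        return (
            self.values.shape == other.values.shape
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.spacing, other.spacing, atol=tol)
        )

    def with_values(self, values: np.ndarray) -> "DoseGrid":
        """A copy of this grid carrying new dose values on the same lattice."""
        return dataclasses.replace(self, values=np.asarray(values, dtype=float))


@dataclass
class ROI:
    """One named structure: a list of closed planar contours.

    Each contour is an (N, 3) array of (x, y, z) vertices in mm, N >= 3,
    with constant z within tolerance (axial planes).
    """

    name: str
    contours: list = field(default_factory=list)


@dataclass
class StructureSet:
    """A set of contoured ROIs sharing one frame of reference."""

    rois: list = field(default_factory=list)
    frame_ref: str = ""

    def names(self) -> list:
        return [r.name for r in self.rois]

    def __getitem__(self, name: str) -> ROI:
        for r in self.rois:
            if r.name == name:
                return r
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(r.name == name for r in self.rois)


@dataclass
class ROIMask:
    """Boolean voxel mask aligned to a reference DoseGrid lattice."""

    grid_ref: DoseGrid
    inside: np.ndarray
    roi_name: str = ""

    def __post_init__(self):
        self.inside = np.asarray(self.inside, dtype=bool)
        if self.inside.shape != self.grid_ref.values.shape:
            raise GridMismatchError(
                f"mask shape {self.inside.shape} != grid shape "
                f"{self.grid_ref.values.shape}"
            )

    @property
    def voxel_count(self) -> int:
        return int(self.inside.sum())

    @property
    def volume_mm3(self) -> float:
        return self.voxel_count * self.grid_ref.voxel_volume_mm3


@dataclass(frozen=True)
class ProtocolSpec:
    """An MV-CBCT imaging protocol: MU per acquisition and fraction count.

    ``gantry_arc`` is acquisition metadata only; no dose computation in this
    package depends on it.
    """

    label: str
    mu_per_fraction: float
    n_fractions: int
    gantry_arc: tuple = (260.0, 100.0)

    def __post_init__(self):
        if self.mu_per_fraction <= 0:
            raise ParameterError("mu_per_fraction must be positive")
        if self.n_fractions < 1:
            raise ParameterError("n_fractions must be >= 1")
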