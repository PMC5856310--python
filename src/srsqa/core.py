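"""Core containers for dose distributions and delineated structures.

A plan is evaluated on a single rectilinear lattice: a :class:`DoseGrid`
holds the absorbed dose in Gy, and each :class:`Structure` holds a boolean
mask aligned voxel-for-voxel with that grid.  All physical lengths are in
mm, doses in Gy, volumes in cm3.  Axis order is (z, y, x); the physical
position of the center of voxel ``(i, j, k)`` is ``origin + (i, j, k) *
spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DoseGrid", "Structure", "ROLES"]

ROLES = ("target", "oar", "healthy_brain", "external")


@dataclass
class DoseGrid:
    """A 3-D scalar field of absorbed dose on a regular lattice.

    Parameters
    ----------
    values
        Dose in Gy, shape (nz, ny, nx).  Must be finite and non-negative.
    spacing
        Physical voxel size in mm per axis, (dz, dy, dx), all > 0.
    origin
        Physical position in mm of the center of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"dose array must be 3-D, got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dose values must be finite")
        if np.any(self.values < 0):
            raise ValueError("dose values must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cm3 (product of spacings / 1000)."""
        return float(np.prod(self.spacing)) / 1000.0

    @classmethod
    def _from_validated(
        cls,
        values: np.ndarray,
        spacing: tuple[float, float, float],
        origin: tuple[float, float, float],
    ) -> "DoseGrid":
        """Internal fast path for arrays already known to be valid doses."""
        obj = object.__new__(cls)
        obj.values = values
        obj.spacing = spacing
        obj.origin = origin
        return obj

    def scaled(self, factor: float) -> "DoseGrid":
        """Return a new grid with every dose multiplied by ``factor``."""
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        return DoseGrid._from_validated(self.values * factor, self.spacing, self.origin)

    def max(self) -> float:
        return float(self.values.max())


@dataclass
class Structure:
    """A named binary mask with a dosimetric role.

    ``prescription_dose`` is required (and > 0) for targets and meaningless
    otherwise.  ``weight`` is the importance factor used by the Radiation
    Planning Index, in [0, 1].
    """

    name: str
    role: str
    mask: np.ndarray
    prescription_dose: float | None = None
    weight: float = 1.0
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("structure mask must be 3-D")
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError(f"weight must lie in [0, 1], got {self.weight}")
        if self.role == "target":
            if self.prescription_dose is None or self.prescription_dose <= 0:
                raise ValueError(
                    f"target {self.name!r} needs a positive prescription dose"
                )

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    def volume_cc(self, grid: DoseGrid) -> float:
        self.require_aligned(grid)
        return self.voxel_count * grid.voxel_volume_cc

    def require_aligned(self, grid: DoseGrid) -> None:
        if self.mask.shape != grid.shape:
            raise ValueError(
                f"structure {self.name!r} mask shape {self.mask.shape} does not "
                f"match grid shape {grid.shape}"
            )

    def require_nonempty(self) -> None:
        if not self.mask.any():
            raise ValueError(f"structure {self.name!r} has an empty mask")

    def doses(self, grid: DoseGrid) -> np.ndarray:
        """Doses of the masked voxels (1-D array)."""
        self.require_aligned(grid)
        return grid.values[self.mask]
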