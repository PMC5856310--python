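"""Cumulative dose-volume histograms and point dose/volume queries.

The cumulative DVH of a structure gives, for each dose level D, the
fraction of the structure's volume receiving at least D.  Internally the
curve is sampled at bin edges 0, w, 2w, ... (w = ``bin_width``), where the
value at each edge is the *exact* voxel count with dose >= edge; queries
between edges interpolate linearly.  The default bin width of 0.01 Gy
gives sub-percent dose resolution at radiosurgical dose levels.

Volume accounting is purely voxel-based: a voxel is in a structure iff its
center is (mask membership); no partial-volume weighting is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .core import DoseGrid, Structure

__all__ = [
    "DVHCurve",
    "compute_cumulative_dvh",
    "dose_at_volume",
    "volume_at_dose",
    "mean_max_dose",
    "sdev_percent",
    "DoseStats",
]

#: Structures with fewer voxels than this are flagged as low-resolution:
#: interpolated Dq% values are then resolved to worse than ~2% of volume.
LOW_RESOLUTION_VOXELS = 50

DEFAULT_BIN_WIDTH = 0.01


@dataclass
class DVHCurve:
    """Cumulative DVH sampled at regular dose bin edges.

    ``rel_volume[i]`` is the percentage of the structure volume receiving
    at least ``bin_edges[i]`` Gy; it starts at 100 and is monotone
    non-increasing, reaching 0 at the first edge above the maximum
    structure dose.  ``max_dose`` / ``min_dose`` record the exact voxel
    extremes so they are not lost to binning.
    """

    bin_edges: np.ndarray
    rel_volume: np.ndarray
    total_volume_cc: float
    max_dose: float
    min_dose: float
    low_resolution: bool = False

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=np.float64)
        self.rel_volume = np.asarray(self.rel_volume, dtype=np.float64)
        if self.bin_edges.shape != self.rel_volume.shape:
            raise ValueError("bin_edges and rel_volume must have equal length")

    @property
    def abs_volume(self) -> np.ndarray:
        """Cumulative volume in cm3 at each bin edge."""
        return self.rel_volume / 100.0 * self.total_volume_cc

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


def compute_cumulative_dvh(
    grid: DoseGrid,
    structure: Structure,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> DVHCurve:
    """Cumulative DVH of ``structure`` on ``grid``.

    Raises ``ValueError`` for an empty mask (the DVH is undefined), a mask
    not aligned with the grid, or a non-positive bin width.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be > 0, got {bin_width}")
    structure.require_aligned(grid)
    structure.require_nonempty()
    doses = np.sort(structure.doses(grid))
    n = doses.size
    dmax = float(doses[-1])
    # edges cover [0, dmax] plus one edge strictly above dmax so the curve
    # visibly reaches 0%
    n_bins = int(np.floor(dmax / bin_width + 1e-9)) + 2
    edges = np.arange(n_bins + 1, dtype=np.float64) * bin_width
    # exact count of voxels with dose >= edge
    ge_counts = n - np.searchsorted(doses, edges, side="left")
    rel = ge_counts.astype(np.float64) / n * 100.0
    return DVHCurve(
        bin_edges=edges,
        rel_volume=rel,
        total_volume_cc=n * grid.voxel_volume_cc,
        max_dose=dmax,
        min_dose=float(doses[0]),
        low_resolution=n < LOW_RESOLUTION_VOXELS,
    )


def dose_at_volume(dvh: DVHCurve, q: float) -> float:
    """D_q%: the minimum dose received by the hottest ``q`` % of the volume.

    Linear interpolation between the bracketing bin edges; ``q`` must lie
    in (0, 100].  D_100% resolves the minimum structure dose to within one
    bin width.
    """
    if not 0.0 < q <= 100.0:
        raise ValueError(f"q must lie in (0, 100], got {q}")
    rel = dvh.rel_volume
    below = np.nonzero(rel < q)[0]
    if below.size == 0:  # pragma: no cover - rel always ends at 0 < q
        return float(dvh.bin_edges[-1])
    i = int(below[0])
    if i == 0:
        return float(dvh.bin_edges[0])
    hi, lo = rel[i - 1], rel[i]
    frac = 0.0 if hi == lo else (hi - q) / (hi - lo)
    return float(dvh.bin_edges[i - 1] + frac * dvh.bin_width)


def volume_at_dose(dvh: DVHCurve, d: float, mode: str = "relative") -> float:
    """V_d: cumulative volume receiving at least ``d`` Gy.

    ``mode='relative'`` returns percent of structure volume,
    ``mode='absolute'`` returns cm3.  ``d`` must be >= 0.
    """
    if d < 0:
        raise ValueError(f"dose must be >= 0, got {d}")
    if mode not in ("relative", "absolute"):
        raise ValueError(f"mode must be 'relative' or 'absolute', got {mode!r}")
    rel = float(np.interp(d, dvh.bin_edges, dvh.rel_volume, right=0.0))
    if mode == "relative":
        return rel
    return rel / 100.0 * dvh.total_volume_cc


class DoseStats(NamedTuple):
    mean_gy: float
    max_gy: float
    d2_gy: float
    """Near-maximum dose D_2%."""
    d1cc_gy: float
    """Minimum dose to the hottest 1 cm3 (max dose if the structure is smaller)."""
    d1cc_is_max: bool


def mean_max_dose(
    grid: DoseGrid,
    structure: Structure,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> DoseStats:
    """Mean, maximum, near-maximum (D_2%) and dose-to-1cm3 of a structure.

    For structures smaller than 1 cm3 (lenses, chiasm on coarse grids) the
    dose-to-1cm3 quantile is undefined and falls back to the maximum dose,
    flagged via ``d1cc_is_max``.
    """
    doses = structure.doses(grid)
    if doses.size == 0:
        raise ValueError(f"structure {structure.name!r} has an empty mask")
    dvh = compute_cumulative_dvh(grid, structure, bin_width)
    mean = float(doses.mean())
    dmax = float(doses.max())
    d2 = dose_at_volume(dvh, 2.0)
    if dvh.total_volume_cc < 1.0:
        return DoseStats(mean, dmax, d2, dmax, True)
    q = 100.0 * 1.0 / dvh.total_volume_cc
    return DoseStats(mean, dmax, d2, dose_at_volume(dvh, q), False)


def sdev_percent(grid: DoseGrid, structure: Structure) -> float:
    """Dose spread of a target as a percentage of its mean dose.

    Population standard deviation of the masked voxel doses divided by the
    masked mean, x100 (a coefficient of variation).  Raises for an empty
    mask or a zero mean dose.
    """
    doses = structure.doses(grid)
    if doses.size == 0:
        raise ValueError(f"structure {structure.name!r} has an empty mask")
    mean = float(doses.mean())
    if mean <= 0:
        raise ValueError(f"structure {structure.name!r} has zero mean dose")
    return float(doses.std(ddof=0)) / mean * 100.0
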