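"""Per-plan quality metrics for multi-target radiosurgery plans.

Covers the standard SRS plan-evaluation panel: near-minimum target dose
(D98%), homogeneity index (D2% - D98%) / prescription, Paddick conformity
index, gradient index, target coverage at 90/100/110% of prescription,
healthy-brain mean dose and V4Gy/V12Gy, and per-OAR dose statistics.

Target metrics are pooled over *all* targets.  When lesions carry
different prescription doses the pooled analysis is carried out on
relative dose: each voxel's dose is divided by the prescription of its
nearest lesion (Euclidean distance to the lesion surface), and the pooled
prescription is 100%.  With a single common prescription the relative
grid is simply dose / prescription and the two conventions coincide.

The prescription isodose volume entering the Paddick indices is taken
over the whole dose grid, not restricted to any anatomy, following the
original definitions.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import DoseGrid, Structure
from .dvh import (
    DEFAULT_BIN_WIDTH,
    DoseStats,
    compute_cumulative_dvh,
    dose_at_volume,
    mean_max_dose,
    sdev_percent,
    volume_at_dose,
)

__all__ = [
    "PlanMetricsRecord",
    "NormalizationResult",
    "total_target",
    "pooled_target_mask",
    "relative_dose_grid",
    "homogeneity_index",
    "paddick_ci",
    "gradient_index",
    "conformity_volumes",
    "normalize_plan",
    "compute_plan_metrics",
]


# ---------------------------------------------------------------------------
# target pooling

def pooled_target_mask(structures: list[Structure]) -> np.ndarray:
    """Voxelwise union of all target masks."""
    targets = [s for s in structures if s.role == "target"]
    if not targets:
        raise ValueError("no target structures given")
    mask = targets[0].mask.copy()
    for s in targets[1:]:
        if s.mask.shape != mask.shape:
            raise ValueError("target masks are not aligned")
        mask |= s.mask
    return mask


def total_target(structures: list[Structure]) -> Structure:
    """Union of all targets as a single target structure.

    Requires a common prescription dose; heterogeneous prescriptions are
    pooled on relative dose instead (see :func:`relative_dose_grid`).
    """
    targets = [s for s in structures if s.role == "target"]
    if not targets:
        raise ValueError("no target structures given")
    prescriptions = {float(s.prescription_dose) for s in targets}
    if len(prescriptions) > 1:
        raise ValueError(
            f"targets carry mixed prescriptions {sorted(prescriptions)}; "
            "pool them on relative dose via relative_dose_grid()"
        )
    return Structure(
        name="total_target",
        role="target",
        mask=pooled_target_mask(structures),
        prescription_dose=prescriptions.pop(),
    )


def relative_dose_grid(grid: DoseGrid, structures: list[Structure]) -> DoseGrid:
    """Dose grid rescaled to percent of the (locally applicable) prescription.

    Every voxel in the grid is assigned to its nearest target (smallest
    Euclidean distance to the target surface, zero inside it) and divided
    by that target's prescription; the result is expressed in % so that
    the pooled prescription level is 100.  With one target, or equal
    prescriptions, this is a plain global division.
    """
    targets = [s for s in structures if s.role == "target"]
    if not targets:
        raise ValueError("no target structures given")
    prescriptions = np.array([float(s.prescription_dose) for s in targets])
    if np.unique(prescriptions).size == 1:
        return DoseGrid(grid.values / prescriptions[0] * 100.0, grid.spacing, grid.origin)
    # nearest-target assignment by distance to each target's surface
    dist = np.empty((len(targets),) + grid.shape, dtype=np.float32)
    for i, s in enumerate(targets):
        s.require_aligned(grid)
        s.require_nonempty()
        dist[i] = ndimage.distance_transform_edt(~s.mask, sampling=grid.spacing)
    assignment = np.argmin(dist, axis=0)
    rx_map = prescriptions[assignment]
    return DoseGrid(grid.values / rx_map * 100.0, grid.spacing, grid.origin)


# ---------------------------------------------------------------------------
# index formulas

def homogeneity_index(d2: float, d98: float, prescription: float) -> float:
    """(D2% - D98%) / prescription; 0 for a perfectly uniform target dose."""
    if prescription <= 0:
        raise ValueError("prescription must be > 0")
    if d2 < d98:
        raise ValueError(f"D2%={d2} < D98%={d98} violates DVH ordering")
    return (d2 - d98) / prescription


def paddick_ci(target_volume_cc: float, piv_cc: float, target_in_piv_cc: float) -> float:
    """Paddick conformity index TV_PIV^2 / (TV x PIV), in (0, 1]."""
    if target_volume_cc <= 0 or piv_cc <= 0:
        raise ValueError("target and prescription isodose volumes must be > 0")
    if target_in_piv_cc < 0:
        raise ValueError("intersection volume must be >= 0")
    if target_in_piv_cc > min(target_volume_cc, piv_cc) * (1 + 1e-12):
        raise ValueError("intersection exceeds one of the intersected volumes")
    return target_in_piv_cc**2 / (target_volume_cc * piv_cc)


def gradient_index(v_half_prescription_cc: float, v_prescription_cc: float) -> float:
    """Half-prescription isodose volume / prescription isodose volume, >= 1."""
    if v_half_prescription_cc <= 0 or v_prescription_cc <= 0:
        raise ValueError("isodose volumes must be > 0")
    if v_half_prescription_cc < v_prescription_cc:
        raise ValueError("half-prescription volume smaller than prescription volume")
    return v_half_prescription_cc / v_prescription_cc


def conformity_volumes(
    rel_grid: DoseGrid, target_mask: np.ndarray
) -> tuple[float, float, float, float]:
    """(TV, PIV, TV^PIV, V50%) in cm3 from voxel counts on a relative grid.

    PIV and V50% are the volumes with relative dose >= 100% and >= 50%,
    counted over the whole grid.
    """
    vox = rel_grid.voxel_volume_cc
    piv_mask = rel_grid.values >= 100.0
    tv = float(target_mask.sum()) * vox
    piv = float(piv_mask.sum()) * vox
    inter = float((piv_mask & target_mask).sum()) * vox
    v_half = float((rel_grid.values >= 50.0).sum()) * vox
    return tv, piv, inter, v_half


# ---------------------------------------------------------------------------
# prescription normalization

@dataclass
class NormalizationResult:
    grid: DoseGrid
    scale: float
    achieved_coverage_pct: float
    converged: bool
    iterations: int


def normalize_plan(
    grid: DoseGrid,
    total_target: Structure,
    coverage: float = 95.0,
    bin_width: float = DEFAULT_BIN_WIDTH,
    tol_pct: float = 0.05,
    max_iter: int = 10,
) -> NormalizationResult:
    """Globally rescale the plan so V_prescription on the target = ``coverage`` %.

    Iterates scale = prescription / D_coverage% until the measured
    coverage is within ``tol_pct`` percentage points.  On plans where the
    exact coverage is unattainable (a dose plateau exactly at the
    prescription level, e.g. a perfectly uniform plan) the fixed point of
    the scale update is returned with ``converged=False``.
    """
    if not 0.0 < coverage <= 100.0:
        raise ValueError(f"coverage must lie in (0, 100], got {coverage}")
    if total_target.role != "target":
        raise ValueError("normalization structure must have role 'target'")
    prescription = float(total_target.prescription_dose)
    total_target.require_aligned(grid)
    total_target.require_nonempty()
    if not np.any(total_target.doses(grid) > 0):
        raise ValueError("target receives zero dose everywhere; cannot normalize")

    doses = np.sort(total_target.doses(grid))

    def measure(s: float) -> float:
        dvh = compute_cumulative_dvh(grid.scaled(s), total_target, bin_width)
        return volume_at_dose(dvh, prescription)

    scale = 1.0
    current = grid
    best: NormalizationResult | None = None
    seen: set[float] = set()
    for it in range(1, max_iter + 1):
        dvh = compute_cumulative_dvh(current, total_target, bin_width)
        achieved = volume_at_dose(dvh, prescription)
        if best is None or abs(achieved - coverage) <= abs(
            best.achieved_coverage_pct - coverage
        ):
            best = NormalizationResult(current, scale, achieved, True, it)
        if abs(achieved - coverage) <= tol_pct:
            return best
        if achieved in seen:
            break  # the quantile update cycles between two binnings
        seen.add(achieved)
        d_cov = dose_at_volume(dvh, coverage)
        if d_cov <= 0:
            raise ValueError("coverage dose level is zero; cannot normalize")
        factor = prescription / d_cov
        if abs(factor - 1.0) < 1e-12:
            break  # plateau fixed point
        scale *= factor
        current = grid.scaled(scale)

    # The quantile iteration resolves the scale only to the voxel-count
    # granularity (~100/n %).  The measured coverage is continuous and
    # monotone in the scale, so refine by bisection around the best iterate.
    lo = hi = best.scale
    v_lo = v_hi = best.achieved_coverage_pct
    for _ in range(60):
        if v_lo < coverage:
            break
        lo *= 0.995
        v_lo = measure(lo)
    for _ in range(60):
        if v_hi > coverage:
            break
        hi *= 1.005
        v_hi = measure(hi)
    refined = best
    if v_lo < coverage < v_hi:
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            v_mid = measure(mid)
            if abs(v_mid - coverage) <= abs(
                refined.achieved_coverage_pct - coverage
            ):
                refined = NormalizationResult(
                    grid.scaled(mid), mid, v_mid, True, refined.iterations
                )
            if abs(v_mid - coverage) <= tol_pct:
                break
            if v_mid < coverage:
                lo = mid
            else:
                hi = mid
    if abs(refined.achieved_coverage_pct - coverage) <= tol_pct:
        # guard against "converging" inside the interpolation cliff of a
        # dose atom (e.g. a perfectly uniform plan): the exact voxel-count
        # coverage must agree with the interpolated one
        count_cov = (
            100.0
            * np.count_nonzero(doses * refined.scale >= prescription)
            / doses.size
        )
        if abs(count_cov - refined.achieved_coverage_pct) <= 2.0:
            return refined
    if abs(best.achieved_coverage_pct - coverage) > 2 * tol_pct:
        warnings.warn(
            f"exact {coverage}% coverage is unattainable for this dose "
            f"distribution; best coverage "
            f"{best.achieved_coverage_pct:.3f}% (flagged)",
            stacklevel=2,
        )
    return dataclasses.replace(best, converged=False)


# ---------------------------------------------------------------------------
# the full per-plan panel

@dataclass
class PlanMetricsRecord:
    """The per-plan metric panel for the three-technique comparison."""

    plan_id: str
    technique: str
    d98_pct: float
    hi: float
    pci: float
    gi: float
    v90_pct: float
    v100_pct: float
    v110_pct: float
    brain_mean_gy: float
    brain_v12_cc: float
    brain_v4_cc: float
    brain_v12_pct: float
    brain_v4_pct: float
    target_volume_cc: float
    piv_cc: float
    sdev_pct: float
    oar_doses: dict[str, DoseStats] = field(default_factory=dict)
    rpi_all: float | None = None
    rpi_targets_brain: float | None = None
    low_resolution: bool = False

    def __post_init__(self) -> None:
        if not (self.v110_pct <= self.v100_pct + 1e-9 and self.v100_pct <= self.v90_pct + 1e-9):
            raise ValueError("coverage must be nested: V110% <= V100% <= V90%")

    def to_row(self) -> dict:
        """Flatten to a single table row (OAR stats expanded per column)."""
        row = {
            "plan_id": self.plan_id,
            "technique": self.technique,
            "d98_pct": self.d98_pct,
            "hi": self.hi,
            "pci": self.pci,
            "gi": self.gi,
            "v90_pct": self.v90_pct,
            "v100_pct": self.v100_pct,
            "v110_pct": self.v110_pct,
            "brain_mean_gy": self.brain_mean_gy,
            "brain_v12_cc": self.brain_v12_cc,
            "brain_v4_cc": self.brain_v4_cc,
            "brain_v12_pct": self.brain_v12_pct,
            "brain_v4_pct": self.brain_v4_pct,
            "target_volume_cc": self.target_volume_cc,
            "piv_cc": self.piv_cc,
            "sdev_pct": self.sdev_pct,
            "rpi_all": self.rpi_all,
            "rpi_targets_brain": self.rpi_targets_brain,
        }
        for name, stats in sorted(self.oar_doses.items()):
            row[f"{name}_mean_gy"] = stats.mean_gy
            row[f"{name}_d2_gy"] = stats.d2_gy
            row[f"{name}_d1cc_gy"] = stats.d1cc_gy
        return row


def _resolve_healthy_brain(
    structures: list[Structure], target_union: np.ndarray
) -> Structure:
    for s in structures:
        if s.role == "healthy_brain":
            return s
    for s in structures:
        if s.name.lower() == "brain":
            return Structure(
                name="healthy_brain",
                role="healthy_brain",
                mask=s.mask & ~target_union,
            )
    raise ValueError(
        "structures must include a 'brain' structure or an explicit "
        "healthy_brain structure"
    )


def compute_plan_metrics(
    grid: DoseGrid,
    structures: list[Structure],
    plan_id: str = "",
    technique: str = "",
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> PlanMetricsRecord:
    """Compute the full metric panel for one plan.

    ``structures`` must contain at least one target and either a whole
    brain (name ``brain``) or an explicit healthy-brain structure; the
    healthy brain is the brain minus the union of the targets.  OAR dose
    statistics are reported for every structure with role ``oar`` except
    the whole brain itself.
    """
    targets = [s for s in structures if s.role == "target"]
    if not targets:
        raise ValueError("plan has no target structures")
    for s in structures:
        s.require_aligned(grid)
    union = pooled_target_mask(structures)
    healthy = _resolve_healthy_brain(structures, union)
    healthy.require_nonempty()

    rel = relative_dose_grid(grid, structures)
    pooled = Structure("total_target", "target", union, prescription_dose=100.0)
    tdvh = compute_cumulative_dvh(rel, pooled, bin_width)
    d98 = dose_at_volume(tdvh, 98.0)
    d2 = dose_at_volume(tdvh, 2.0)
    hi = homogeneity_index(d2, d98, 100.0)
    v90 = volume_at_dose(tdvh, 90.0)
    v100 = volume_at_dose(tdvh, 100.0)
    v110 = volume_at_dose(tdvh, 110.0)

    tv, piv, inter, v_half = conformity_volumes(rel, union)
    pci = paddick_ci(tv, piv, inter)
    gi = gradient_index(v_half, piv)

    bdvh = compute_cumulative_dvh(grid, healthy, bin_width)
    brain_mean = float(healthy.doses(grid).mean())
    brain_v12_cc = volume_at_dose(bdvh, 12.0, mode="absolute")
    brain_v4_cc = volume_at_dose(bdvh, 4.0, mode="absolute")
    brain_v12_pct = volume_at_dose(bdvh, 12.0)
    brain_v4_pct = volume_at_dose(bdvh, 4.0)

    oar_doses = {
        s.name: mean_max_dose(grid, s, bin_width)
        for s in structures
        if s.role == "oar" and s.name.lower() != "brain" and s.mask.any()
    }

    return PlanMetricsRecord(
        plan_id=plan_id,
        technique=technique,
        d98_pct=d98,
        hi=hi,
        pci=pci,
        gi=gi,
        v90_pct=v90,
        v100_pct=v100,
        v110_pct=v110,
        brain_mean_gy=brain_mean,
        brain_v12_cc=brain_v12_cc,
        brain_v4_cc=brain_v4_cc,
        brain_v12_pct=brain_v12_pct,
        brain_v4_pct=brain_v4_pct,
        target_volume_cc=tv,
        piv_cc=piv,
        sdev_pct=sdev_percent(rel, pooled),
        oar_doses=oar_doses,
        low_resolution=tdvh.low_resolution,
    )
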