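"""The Radiation Planning Index (RPI): a composite plan-quality score.

The RPI condenses a plan into one number in [0, 1] from the cumulative
DVHs of its targets and organs at risk.  For each structure the relevant
quantity is the normalized area under its cumulative relative-volume DVH,

    A = (integral of V(D) dD from 0 to D_max) / (100 * D_max),

where D_max is the maximum dose that structure receives *among all the
plans being compared* (so that competing plans are scored on a common
dose axis).  A is 1 for a structure uniformly covered at D_max and 0 for
an unirradiated structure.  With k targets (index j) and n OARs (index
i), each carrying an importance weight W in [0, 1], the score is

    RPI = [ prod_j prod_i (1 - W_i * A_i) * A_j * (1 - SDev_j/100 * W_j) ]^(1/(k+n))

with SDev_j the target dose spread in percent.  An ideal plan (OARs
unirradiated, targets uniformly covered, SDev = 0) scores exactly 1; a
plan whose OARs are uniformly flooded at the maximal dose with weight 1
scores exactly 0.

The printed form repeats the target factor once per OAR inside the
double product; an alternate ``variant="per_structure"`` applies one
factor per structure (a plain geometric mean over the k+n factors) for
sensitivity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dvh import DVHCurve

__all__ = [
    "RPIStructureTerm",
    "RPIResult",
    "integral_dvh_area",
    "compute_rpi",
    "cross_plan_dmax",
]


@dataclass
class RPIStructureTerm:
    """One structure's contribution to the RPI."""

    name: str
    kind: str  # "target" | "oar"
    dvh: DVHCurve
    d_max_across_plans: float
    weight: float = 1.0
    sdev_pct: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("target", "oar"):
            raise ValueError(f"kind must be 'target' or 'oar', got {self.kind!r}")
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError(f"weight must lie in [0, 1], got {self.weight}")
        if self.sdev_pct < 0:
            raise ValueError("sdev_pct must be >= 0")
        if self.d_max_across_plans < self.dvh.max_dose - 1e-9:
            raise ValueError(
                f"{self.name!r}: cross-plan maximum {self.d_max_across_plans} is "
                f"below this plan's own maximum {self.dvh.max_dose}"
            )


@dataclass
class RPIResult:
    rpi: float
    per_term_factors: dict = field(default_factory=dict)
    k: int = 0
    n: int = 0
    variant: str = "printed"


def integral_dvh_area(dvh: DVHCurve, d_max: float) -> float:
    """Normalized area under the cumulative relative-volume DVH on [0, d_max].

    Trapezoidal integration on the DVH bin grid, extended with zeros up to
    ``d_max`` (the cross-plan maximum) and divided by 100 * d_max; the
    result lies in [0, 1].  A structure receiving no dose at all has area
    exactly 0 (its DVH is a zero-width step at D = 0).
    """
    if dvh.max_dose == 0.0 and d_max == 0.0:
        # the structure is unirradiated in every compared plan
        return 0.0
    if d_max <= 0:
        raise ValueError("d_max must be > 0")
    if d_max < dvh.max_dose - 1e-9:
        raise ValueError(
            f"d_max={d_max} is below the structure's maximum dose {dvh.max_dose}; "
            "the cross-plan maximum can never be smaller than the plan's own"
        )
    if dvh.max_dose == 0.0:
        return 0.0
    if dvh.min_dose == dvh.max_dose and d_max == dvh.max_dose:
        # homogeneous coverage exactly at the cross-plan maximum: the DVH
        # is a full rectangle and the ratio is exactly 1
        return 1.0
    edges = dvh.bin_edges
    rel = dvh.rel_volume
    # integrate only up to min(d_max, last edge); beyond the curve is 0
    upper = min(d_max, float(edges[-1]))
    if upper < float(edges[-1]):
        rel_at_upper = np.interp(upper, edges, rel)
        keep = edges <= upper
        edges = np.append(edges[keep], upper)
        rel = np.append(rel[keep], rel_at_upper)
    area = float(np.trapezoid(rel, edges))
    return area / (100.0 * d_max)


def compute_rpi(
    targets: list[RPIStructureTerm],
    oars: list[RPIStructureTerm],
    variant: str = "printed",
) -> RPIResult:
    """Evaluate the RPI from per-structure DVH terms.

    ``variant="printed"`` follows the published double-product form
    (k x n bracketed factors under a (k+n)-th root; with n = 0 the k
    target factors under a k-th root).  ``variant="per_structure"``
    applies one factor per structure instead.
    """
    if variant not in ("printed", "per_structure"):
        raise ValueError(f"unknown variant {variant!r}")
    k, n = len(targets), len(oars)
    if k < 1:
        raise ValueError("RPI needs at least one target structure")
    for t in targets:
        if t.kind != "target":
            raise ValueError(f"{t.name!r} passed as target but kind={t.kind!r}")
    for o in oars:
        if o.kind != "oar":
            raise ValueError(f"{o.name!r} passed as OAR but kind={o.kind!r}")

    oar_factors = {
        o.name: 1.0 - o.weight * integral_dvh_area(o.dvh, o.d_max_across_plans)
        for o in oars
    }
    target_factors = {
        t.name: integral_dvh_area(t.dvh, t.d_max_across_plans)
        * (1.0 - t.sdev_pct / 100.0 * t.weight)
        for t in targets
    }
    for name, f in {**oar_factors, **target_factors}.items():
        if f < 0:
            raise ValueError(
                f"negative RPI factor for {name!r} ({f}); inputs violate the "
                "weight/SDev invariants"
            )

    factors: dict = {}
    if variant == "printed":
        if n == 0:
            factors = dict(target_factors)
        else:
            for t in targets:
                for o in oars:
                    factors[(t.name, o.name)] = oar_factors[o.name] * target_factors[t.name]
    else:
        factors = {**target_factors, **oar_factors}

    log_or_zero = [f for f in factors.values()]
    if any(f == 0.0 for f in log_or_zero):
        rpi = 0.0
    else:
        # geometric aggregation in log space for numerical stability
        rpi = float(np.exp(np.sum(np.log(list(factors.values()))) / (k + n)))
    return RPIResult(rpi=rpi, per_term_factors=factors, k=k, n=n, variant=variant)


def cross_plan_dmax(plans: list[tuple[str, dict[str, DVHCurve]]]) -> dict[str, float]:
    """Per-structure maximum dose across all compared plans.

    ``plans`` is a list of (plan_id, {structure_name: DVHCurve}).  Every
    plan's RPI term for a structure must use this shared maximum so the
    plans are scored on a common dose axis.  A structure appearing in only
    one plan triggers a warning and uses its own maximum.
    """
    if not plans:
        raise ValueError("no plans given")
    maxima: dict[str, list[float]] = {}
    for _plan_id, dvhs in plans:
        for name, dvh in dvhs.items():
            maxima.setdefault(name, []).append(dvh.max_dose)
    n_plans = len(plans)
    out = {}
    for name, values in maxima.items():
        if n_plans > 1 and len(values) == 1:
            warnings.warn(
                f"structure {name!r} present in a single plan; using its own "
                "maximum dose",
                stacklevel=2,
            )
        out[name] = max(values)
    return out
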