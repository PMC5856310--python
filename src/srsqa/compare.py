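"""Three-technique cohort comparison: metric tables and rank tests.

For every patient x technique the pipeline renders the synthetic plan,
computes the per-plan metric panel and the RPI (in two variants: scored
over all structures, and over the targets plus healthy brain only), and
then compares the techniques metric-by-metric with nonparametric
Kruskal-Wallis tests at a significance threshold of 0.05.  When the
omnibus test is significant for more than two groups, pairwise two-group
tests are run as a post-hoc (uncorrected by default; Holm correction
available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import DoseGrid, Structure
from .dvh import DEFAULT_BIN_WIDTH, compute_cumulative_dvh, sdev_percent
from .metrics import compute_plan_metrics, pooled_target_mask, relative_dose_grid
from .rpi import RPIStructureTerm, compute_rpi, cross_plan_dmax
from .synthetic import SyntheticPatientSpec, TechniqueProfile, render_dose

__all__ = [
    "ComparisonResult",
    "kruskal_wallis",
    "summarize_boxplot_stats",
    "BoxplotStats",
    "plan_rpi_inputs",
    "run_comparison",
    "ALPHA",
]

logger = logging.getLogger(__name__)

ALPHA = 0.05

#: RPI OAR set when scoring is restricted to the primary structures.
TARGETS_BRAIN_OARS = ("healthy_brain",)


def kruskal_wallis(groups: list[list[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; p from the chi-square approximation.

    Groups that are entirely tied (every value identical across all
    groups) carry no rank information: H = 0 and p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(pooled == pooled[0]):
        # complete ties carry no rank information, whatever the group sizes
        return 0.0, 1.0
    for g in groups:
        if len(g) < 2:
            raise ValueError("every group needs at least two values")
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


class BoxplotStats(NamedTuple):
    mean: float
    sd: float
    se: float
    median: float
    q1: float
    q3: float


def summarize_boxplot_stats(values: list[float]) -> BoxplotStats:
    """Descriptive statistics for a boxplot panel (sd with n-1 denominator)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    sd = float(v.std(ddof=1))
    return BoxplotStats(
        mean=float(v.mean()),
        sd=sd,
        se=sd / np.sqrt(v.size),
        median=float(np.median(v)),
        q1=float(np.percentile(v, 25)),
        q3=float(np.percentile(v, 75)),
    )


@dataclass
class ComparisonResult:
    metric: str
    groups: dict[str, list[float]]
    medians: dict[str, float]
    means: dict[str, float]
    sds: dict[str, float]
    h_statistic: float
    p_value: float
    significant: bool
    pairwise_p: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "groups": {k: list(map(float, v)) for k, v in self.groups.items()},
            "medians": self.medians,
            "means": self.means,
            "sds": self.sds,
            "h_statistic": self.h_statistic,
            "p_value": self.p_value,
            "significant": self.significant,
            "pairwise_p": self.pairwise_p,
        }


def plan_rpi_inputs(
    grid: DoseGrid,
    structures: list[Structure],
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> tuple[dict, float]:
    """DVHs (absolute dose) and target dose spread needed for the RPI.

    Returns ``({structure_name: DVHCurve}, sdev_pct)`` where the dict
    contains the pooled target under the name ``total_target`` plus every
    OAR and the healthy brain.  The target dose spread is computed on
    relative dose so heterogeneous prescriptions pool consistently.
    """
    union = pooled_target_mask(structures)
    pooled = Structure("total_target", "target", union, prescription_dose=1.0)
    dvhs = {"total_target": compute_cumulative_dvh(grid, pooled, bin_width)}
    for s in structures:
        if s.role in ("oar", "healthy_brain") and s.name.lower() != "brain" and s.mask.any():
            dvhs[s.name] = compute_cumulative_dvh(grid, s, bin_width)
    rel = relative_dose_grid(grid, structures)
    rel_pooled = Structure("total_target", "target", union, prescription_dose=100.0)
    return dvhs, sdev_percent(rel, rel_pooled)


def _patient_rpis(
    plan_dvhs: dict[str, dict],
    plan_sdev: dict[str, float],
    weights: dict[str, float],
    variant: str,
) -> dict[str, tuple[float, float]]:
    """Per-technique (rpi_all, rpi_targets_brain) for one patient."""
    dmax = cross_plan_dmax(list(plan_dvhs.items()))
    out = {}
    for tech, dvhs in plan_dvhs.items():
        target_term = RPIStructureTerm(
            name="total_target",
            kind="target",
            dvh=dvhs["total_target"],
            d_max_across_plans=dmax["total_target"],
            weight=weights.get("total_target", 1.0),
            sdev_pct=plan_sdev[tech],
        )
        all_oars = [
            RPIStructureTerm(
                name=name, kind="oar", dvh=dvh,
                d_max_across_plans=dmax[name],
                weight=weights.get(name, 1.0),
            )
            for name, dvh in dvhs.items()
            if name != "total_target"
        ]
        brain_oars = [o for o in all_oars if o.name in TARGETS_BRAIN_OARS]
        rpi_all = compute_rpi([target_term], all_oars, variant=variant).rpi
        rpi_tb = compute_rpi([target_term], brain_oars, variant=variant).rpi
        out[tech] = (rpi_all, rpi_tb)
    return out


def run_comparison(
    cohort: list[SyntheticPatientSpec],
    profiles: dict[str, TechniqueProfile],
    seed: int,
    bin_width: float = DEFAULT_BIN_WIDTH,
    weights: dict[str, float] | None = None,
    rpi_variant: str = "printed",
    holm: bool = False,
) -> tuple[pd.DataFrame, list[ComparisonResult]]:
    """Render and score every patient x technique, then compare techniques.

    Returns the per-plan metric table (one row per patient x technique)
    and one :class:`ComparisonResult` per numeric metric.  Fully
    reproducible given ``seed``: per-plan noise streams are derived from
    (seed, patient index, technique index).
    """
    if not cohort:
        raise ValueError("cohort is empty")
    if len(profiles) < 2:
        raise ValueError("need at least two technique profiles")
    weights = weights or {}

    rows = []
    for p_idx, spec in enumerate(cohort):
        plan_dvhs: dict[str, dict] = {}
        plan_sdev: dict[str, float] = {}
        plan_records = {}
        for t_idx, (tech, profile) in enumerate(profiles.items()):
            plan_seed = int(
                np.random.SeedSequence((seed, p_idx, t_idx)).generate_state(1)[0]
                % 2**31
            )
            logger.info("rendering %s / %s", spec.patient_id, tech)
            try:
                grid, structures = render_dose(spec, profile, seed=plan_seed)
                record = compute_plan_metrics(
                    grid, structures, plan_id=spec.patient_id,
                    technique=tech, bin_width=bin_width,
                )
                dvhs, sdev = plan_rpi_inputs(grid, structures, bin_width)
            except Exception as err:
                raise RuntimeError(
                    f"failed on patient {spec.patient_id}, technique {tech}: {err}"
                ) from err
            plan_dvhs[tech] = dvhs
            plan_sdev[tech] = sdev
            plan_records[tech] = record
        for tech, (rpi_all, rpi_tb) in _patient_rpis(
            plan_dvhs, plan_sdev, weights, rpi_variant
        ).items():
            plan_records[tech].rpi_all = rpi_all
            plan_records[tech].rpi_targets_brain = rpi_tb
        rows.extend(r.to_row() for r in plan_records.values())

    table = pd.DataFrame(rows)
    results = compare_metric_table(table, holm=holm)
    return table, results


def compare_metric_table(
    table: pd.DataFrame, holm: bool = False
) -> list[ComparisonResult]:
    """One Kruskal-Wallis comparison per numeric metric column."""
    techniques = list(dict.fromkeys(table["technique"]))
    metric_cols = [
        c for c in table.columns
        if c not in ("plan_id", "technique")
        and pd.api.types.is_numeric_dtype(table[c])
        and table[c].notna().any()  # e.g. RPI columns not yet filled
    ]
    results = []
    for metric in metric_cols:
        groups = {
            tech: table.loc[table["technique"] == tech, metric].astype(float).tolist()
            for tech in techniques
        }
        values = list(groups.values())
        h, p = kruskal_wallis(values)
        significant = p < ALPHA
        pairwise: dict[str, float] = {}
        if significant and len(techniques) > 2:
            pairs = list(combinations(techniques, 2))
            raw = [kruskal_wallis([groups[a], groups[b]])[1] for a, b in pairs]
            if holm:
                order = np.argsort(raw)
                m = len(raw)
                adj = np.empty(m)
                running = 0.0
                for rank, idx in enumerate(order):
                    running = max(running, (m - rank) * raw[idx])
                    adj[idx] = min(1.0, running)
                raw = list(adj)
            pairwise = {f"{a} vs {b}": float(q) for (a, b), q in zip(pairs, raw)}
        results.append(
            ComparisonResult(
                metric=metric,
                groups=groups,
                medians={t: float(np.median(g)) for t, g in groups.items()},
                means={t: float(np.mean(g)) for t, g in groups.items()},
                sds={
                    t: float(np.std(g, ddof=1)) if len(g) > 1 else float("nan")
                    for t, g in groups.items()
                },
                h_statistic=h,
                p_value=p,
                significant=significant,
                pairwise_p=pairwise,
            )
        )
    return results
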