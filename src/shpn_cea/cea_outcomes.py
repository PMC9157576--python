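"""Incremental cost-effectiveness outcomes.

Primary analysis: total discounted cost and QALYs per arm from the cohort
trace, increments ΔC and ΔE, the ICER = ΔC/ΔE with a dominance class, the
net monetary benefit NMB(λ) = λ·ΔE − ΔC at a willingness-to-pay λ, and the
cost headroom λ·ΔE − ΔC (the largest extra one-time intervention cost that
keeps the ICER at or below λ).

Secondary analysis: ICERs per effect metric (quality of life, BMI, fat-free
mass and its index, handgrip strength, 6-minute walk) at each 6-week visit.
ΔE at visit v is the between-arm difference in change from baseline; ΔC is
the incremental cost accumulated from model start through the visit-v time
point (cycles 0..v−2).  Because the effect metrics are measured in patients
who attend the visit — i.e. survivors — the matching cost is the
*per-surviving-patient* cost: recurring items accrue at full weight over the
elapsed cycles (a survivor paid every cycle's cost), discounted as in the
primary analysis.  A ``costing="cohort"`` switch instead uses the
alive-weighted cohort trace increments.

A convention scan re-runs the base case over candidate time-unit and
treatment-duration conventions and reports the one closest to a published
reference, since the time unit of the published Weibull parameters is not
stated with them.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd

from .markov_engine import evaluate_arm
from .parameters_io import (
    METRIC_UNITS,
    ArmSpec,
    EffectDelta,
    ModelConfig,
    apply_conventions,
)

__all__ = [
    "CEAResult",
    "SecondaryICER",
    "compute_icer",
    "nmb",
    "headroom",
    "run_cea",
    "secondary_delta_cost",
    "secondary_icer",
    "qol_effect_from_config",
    "secondary_table",
    "convention_scan",
]


@dataclass(frozen=True)
class CEAResult:
    """Paired-arm totals, increments, ICER and dominance classification.

    ``dominance`` is one of ``dominant`` (intervention cheaper and more
    effective), ``dominated`` (dearer and less effective), ``tradeoff_NE``
    (dearer, more effective) or ``tradeoff_SW`` (cheaper, less effective);
    ``icer`` is meaningful only for the trade-off classes and is NaN when
    ΔE = 0 (``icer_defined`` False).
    """

    arm_names: tuple[str, str]
    costs: tuple[float, float]
    effects: tuple[float, float]
    delta_cost: float
    delta_effect: float
    icer: float
    icer_defined: bool
    dominance: str
    effect_unit: str = "QALY"
    wtp: float | None = None

    @property
    def nmb(self) -> float | None:
        if self.wtp is None:
            return None
        return nmb(self.wtp, self.delta_effect, self.delta_cost)

    @property
    def headroom(self) -> float | None:
        if self.wtp is None or self.delta_effect <= 0:
            return None
        return headroom(self.wtp, self.delta_effect, self.delta_cost)

    def frame(self) -> pd.DataFrame:
        rows = []
        for i, name in enumerate(self.arm_names):
            first = i == 0
            rows.append(
                {
                    "arm": name,
                    "cost": self.costs[i],
                    "qaly": self.effects[i],
                    "d_cost": self.delta_cost if first else np.nan,
                    "d_qaly": self.delta_effect if first else np.nan,
                    "icer": (self.icer if first and self.icer_defined else np.nan),
                    "dominance": self.dominance if first else "",
                }
            )
        return pd.DataFrame(
            rows, columns=["arm", "cost", "qaly", "d_cost", "d_qaly", "icer", "dominance"]
        )

    def summary(self) -> dict[str, Any]:
        out: dict[str, Any] = {
            "arms": list(self.arm_names),
            "costs": list(self.costs),
            "effects": list(self.effects),
            "effect_unit": self.effect_unit,
            "delta_cost": self.delta_cost,
            "delta_effect": self.delta_effect,
            "icer": self.icer if self.icer_defined else None,
            "dominance": self.dominance,
        }
        if self.wtp is not None:
            out["wtp"] = self.wtp
            out["nmb"] = self.nmb
            out["headroom"] = self.headroom
        return out


def compute_icer(
    c1: float,
    c0: float,
    e1: float,
    e0: float,
    effect_unit: str = "QALY",
    arm_names: tuple[str, str] = ("intervention", "comparator"),
    wtp: float | None = None,
) -> CEAResult:
    """Incremental comparison of (c1, e1) against comparator (c0, e0)."""
    dc = c1 - c0
    de = e1 - e0
    if dc < 0 and de > 0:
        dominance = "dominant"
    elif dc > 0 and de < 0:
        dominance = "dominated"
    elif de >= 0:
        dominance = "tradeoff_NE"
    else:
        dominance = "tradeoff_SW"
    defined = de != 0.0
    icer = dc / de if defined else math.nan
    return CEAResult(
        arm_names=arm_names,
        costs=(c1, c0),
        effects=(e1, e0),
        delta_cost=dc,
        delta_effect=de,
        icer=icer,
        icer_defined=defined,
        dominance=dominance,
        effect_unit=effect_unit,
        wtp=wtp,
    )


def nmb(wtp: float, delta_e: float, delta_c: float) -> float:
    """Net monetary benefit: wtp*ΔE − ΔC ($)."""
    return wtp * delta_e - delta_c


def headroom(wtp: float, delta_e: float, delta_c: float) -> float:
    """Largest extra one-time intervention cost keeping ICER ≤ wtp.

    Defined only for ΔE > 0; algebraically equal to the net monetary
    benefit at the threshold.
    """
    if delta_e <= 0:
        raise ValueError("headroom is undefined for delta_e <= 0")
    return wtp * delta_e - delta_c


def run_cea(
    config: ModelConfig,
    time_unit_days: float | None = None,
    treatment_cycles: int | None = None,
    utility_mapping: str = "visit_end",
    half_cycle: bool = False,
) -> CEAResult:
    """Full base-case analysis of the configured pair of arms."""
    cfg = apply_conventions(config, time_unit_days, treatment_cycles)
    _, c1, e1 = evaluate_arm(cfg.intervention, cfg.cycle, utility_mapping, half_cycle)
    _, c0, e0 = evaluate_arm(cfg.comparator, cfg.cycle, utility_mapping, half_cycle)
    return compute_icer(
        c1,
        c0,
        e1,
        e0,
        arm_names=(cfg.intervention.name, cfg.comparator.name),
        wtp=cfg.wtp,
    )


# ---------------------------------------------------------------------------
# Secondary per-visit, multi-metric ICERs
# ---------------------------------------------------------------------------


def _per_survivor_cost(arm: ArmSpec, cycle: Any, n_cycles: int) -> float:
    """Discounted cost per patient surviving the first ``n_cycles`` cycles."""
    total = 0.0
    for item in arm.costs:
        if item.recurrence == "once":
            if item.applies_from_cycle < n_cycles:
                total += item.amount * cycle.discount_factor(item.applies_from_cycle)
        else:
            lo = item.applies_from_cycle
            hi = (
                n_cycles - 1
                if item.applies_through_cycle is None
                else min(item.applies_through_cycle, n_cycles - 1)
            )
            for k in range(lo, hi + 1):
                total += item.amount * cycle.discount_factor(k)
    return total


def secondary_delta_cost(
    config: ModelConfig,
    visit: int,
    costing: str = "per_survivor",
    time_unit_days: float | None = None,
    treatment_cycles: int | None = None,
) -> float:
    """Incremental discounted cost from model start through visit ``visit``.

    Visit v closes cycle v−2, so v−1 cycles have elapsed (visit 2 = one
    cycle).  ``per_survivor`` accrues recurring items at full weight (the
    cost actually paid by a patient alive at the visit); ``cohort`` uses the
    alive-weighted trace increments.
    """
    if not 2 <= visit <= 5:
        raise ValueError(f"visit must be in 2..5, got {visit}")
    cfg = apply_conventions(config, time_unit_days, treatment_cycles)
    n_cycles = visit - 1
    if costing == "per_survivor":
        c1 = _per_survivor_cost(cfg.intervention, cfg.cycle, n_cycles)
        c0 = _per_survivor_cost(cfg.comparator, cfg.cycle, n_cycles)
        return c1 - c0
    if costing == "cohort":
        tr1, _, _ = evaluate_arm(cfg.intervention, cfg.cycle)
        tr0, _, _ = evaluate_arm(cfg.comparator, cfg.cycle)
        return float(tr1.cost_inc[:n_cycles].sum() - tr0.cost_inc[:n_cycles].sum())
    raise ValueError(f"unknown costing '{costing}'")


@dataclass(frozen=True)
class SecondaryICER:
    """One cell of the secondary analysis: metric × visit."""

    metric: str
    unit: str
    visit: int
    delta_cost: float
    delta_effect: float
    icer: float
    icer_defined: bool


def qol_effect_from_config(config: ModelConfig) -> EffectDelta:
    """Quality-of-life changes from baseline implied by the utility schedules."""
    changes = {
        arm.name: tuple(
            arm.utilities.at_visit(v) - arm.utilities.baseline for v in range(2, 6)
        )
        for arm in config.arms
    }
    return EffectDelta(metric="Qol", unit=METRIC_UNITS["Qol"], changes=changes)


def secondary_icer(
    effect: EffectDelta,
    visit: int,
    config: ModelConfig,
    costing: str = "per_survivor",
    **conventions: Any,
) -> SecondaryICER:
    """ICER ($ per metric unit) for one effect metric at one visit.

    Negative ratios are passed through with their sign (they arise when the
    intervention is *worse* on the metric while costing more) — the
    ``icer_defined`` flag only marks ΔE = 0.
    """
    d_cost = secondary_delta_cost(config, visit, costing=costing, **conventions)
    e1 = effect.change_at(config.intervention.name, visit)
    e0 = effect.change_at(config.comparator.name, visit)
    d_eff = e1 - e0
    defined = d_eff != 0.0
    return SecondaryICER(
        metric=effect.metric,
        unit=effect.unit,
        visit=visit,
        delta_cost=d_cost,
        delta_effect=d_eff,
        icer=d_cost / d_eff if defined else math.nan,
        icer_defined=defined,
    )


def secondary_table(
    effects: Iterable[EffectDelta],
    config: ModelConfig,
    costing: str = "per_survivor",
    **conventions: Any,
) -> pd.DataFrame:
    """Visit × metric ICER matrix (rows: visits 2-5; columns: metrics)."""
    effects = list(effects)
    data = {
        e.metric: [
            secondary_icer(e, v, config, costing=costing, **conventions).icer
            for v in range(2, 6)
        ]
        for e in effects
    }
    frame = pd.DataFrame(data, index=pd.Index(range(2, 6), name="visit"))
    return frame.reset_index()


# ---------------------------------------------------------------------------
# Convention scan
# ---------------------------------------------------------------------------


def convention_scan(
    config: ModelConfig,
    reference: Mapping[str, Any] | None = None,
    time_units: Iterable[float] = (7.0, 14.0, 42.0),
    treatment_cycles: Iterable[int | None] = (4, None),
) -> pd.DataFrame:
    """Base-case results under each accrual convention, ranked by discrepancy.

    ``reference`` is a mapping like the fixture's ``reference_results.table2``
    (per-arm cost/qaly plus icer); when omitted it is taken from the config's
    reference metadata.  Discrepancy is the maximum relative deviation over
    the five reference quantities; rows are sorted ascending, so row 0 is the
    convention that best reproduces the reference.
    """
    if reference is None:
        if not config.reference_results or "table2" not in config.reference_results:
            raise ValueError("no reference results available for the scan")
        reference = config.reference_results["table2"]
    name1, name0 = config.intervention.name, config.comparator.name
    ref = {
        "cost_1": float(reference[name1]["cost"]),
        "qaly_1": float(reference[name1]["qaly"]),
        "cost_0": float(reference[name0]["cost"]),
        "qaly_0": float(reference[name0]["qaly"]),
        "icer": float(reference["icer"]),
    }
    rows = []
    for tu, tc in itertools.product(time_units, treatment_cycles):
        res = run_cea(config, time_unit_days=tu, treatment_cycles=tc)
        model = {
            "cost_1": res.costs[0],
            "qaly_1": res.effects[0],
            "cost_0": res.costs[1],
            "qaly_0": res.effects[1],
            "icer": res.icer,
        }
        rows.append(
            {
                "time_unit_days": tu,
                "treatment_cycles": np.nan if tc is None else tc,
                **model,
                "d_cost": res.delta_cost,
                "d_qaly": res.delta_effect,
                "max_rel_discrepancy": max(
                    abs(model[k] / ref[k] - 1.0) for k in ref
                ),
            }
        )
    frame = pd.DataFrame(rows).sort_values("max_rel_discrepancy", ignore_index=True)
    return frame
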