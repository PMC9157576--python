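"""Two-state (survive/die) Markov cohort trace with discounted accrual.

The cohort starts fully alive; during cycle ``k`` (0-indexed) the fraction
alive at the cycle start is exactly ``S(k*u)`` because the per-cycle death
probabilities telescope against the Weibull survival function.  Costs and
QALYs accrue per cycle, weighted by the alive fraction at cycle start (no
half-cycle correction in the reference convention — a ``half_cycle`` switch
averages start/end membership instead), and are discounted at the annual
rate pro-rated by exact day counts: ``(1+r)^(-k * cycle_days / 365.25)``.

One-time costs accrue at their start cycle (cycle 0 by default: full cohort
weight, no discount); recurring costs accrue every cycle inside their
applicability window.  Cycle ``k`` maps to the utility measured at the visit
closing it (visit k+2), with the last visit carried forward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters_io import ArmSpec, CostItem, CycleSpec
from .survival import survival_at, transition_probability

__all__ = ["MarkovTrace", "run_trace", "accrue_costs", "accrue_qalys", "evaluate_arm"]


@dataclass
class MarkovTrace:
    """Cycle-indexed cohort membership and (once accrued) value increments.

    ``alive[k]`` is the fraction alive at the start of cycle k; ``p_death[k]``
    the death probability applied during cycle k; ``alive_end[k]`` the
    fraction alive at its end.  ``cost_inc``/``qaly_inc`` hold discounted
    per-cycle increments after the accrual passes ran.
    """

    cycle: np.ndarray
    alive: np.ndarray
    p_death: np.ndarray
    alive_end: np.ndarray
    cost_inc: np.ndarray = field(default=None)  # type: ignore[assignment]
    qaly_inc: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.cycle)
        if self.cost_inc is None:
            self.cost_inc = np.zeros(n)
        if self.qaly_inc is None:
            self.qaly_inc = np.zeros(n)

    @property
    def dead(self) -> np.ndarray:
        """Cumulative dead fraction at each cycle start."""
        return 1.0 - self.alive

    @property
    def total_cost(self) -> float:
        return float(self.cost_inc.sum())

    @property
    def total_qaly(self) -> float:
        return float(self.qaly_inc.sum())

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": self.cycle,
                "alive": self.alive,
                "p_death": self.p_death,
                "cost_inc": self.cost_inc,
                "qaly_inc": self.qaly_inc,
                "cum_cost": np.cumsum(self.cost_inc),
                "cum_qaly": np.cumsum(self.qaly_inc),
            }
        )


def run_trace(arm: ArmSpec, cycle: CycleSpec) -> MarkovTrace:
    """Run the cohort through ``horizon_cycles`` cycles of the two-state model."""
    u = cycle.u_for(arm.survival)
    h = cycle.horizon_cycles
    k = np.arange(h)
    p_death = np.array(
        [transition_probability(arm.survival, (i + 1) * u, u) for i in k]
    )
    # alive-at-start follows from the telescoping product of (1 - p_death)
    alive = np.empty(h)
    alive[0] = 1.0
    for i in range(1, h):
        alive[i] = alive[i - 1] * (1.0 - p_death[i - 1])
    alive_end = alive * (1.0 - p_death)
    return MarkovTrace(cycle=k, alive=alive, p_death=p_death, alive_end=alive_end)


def _membership_weights(trace: MarkovTrace, half_cycle: bool) -> np.ndarray:
    if half_cycle:
        return 0.5 * (trace.alive + trace.alive_end)
    return trace.alive


def _cost_window(item: CostItem, horizon: int) -> np.ndarray:
    lo = item.applies_from_cycle
    hi = horizon - 1 if item.applies_through_cycle is None else min(
        item.applies_through_cycle, horizon - 1
    )
    mask = np.zeros(horizon, dtype=bool)
    if lo <= hi:
        mask[lo : hi + 1] = True
    return mask


def accrue_costs(
    trace: MarkovTrace,
    arm: ArmSpec,
    cycle: CycleSpec,
    half_cycle: bool = False,
) -> float:
    """Total discounted cost ($); also fills ``trace.cost_inc`` per cycle."""
    h = cycle.horizon_cycles
    disc = cycle.discount_factor(trace.cycle)
    weights = _membership_weights(trace, half_cycle)
    inc = np.zeros(h)
    for item in arm.costs:
        if item.recurrence == "once":
            a = item.applies_from_cycle
            if a < h:
                inc[a] += item.amount * trace.alive[a] * disc[a]
        else:
            mask = _cost_window(item, h)
            inc[mask] += item.amount * weights[mask] * disc[mask]
    trace.cost_inc = inc
    return float(inc.sum())


def accrue_qalys(
    trace: MarkovTrace,
    arm: ArmSpec,
    cycle: CycleSpec,
    utility_mapping: str = "visit_end",
    half_cycle: bool = False,
) -> float:
    """Total discounted QALYs; also fills ``trace.qaly_inc`` per cycle."""
    disc = cycle.discount_factor(trace.cycle)
    weights = _membership_weights(trace, half_cycle)
    utils = np.array(
        [arm.utilities.for_cycle(int(k), utility_mapping) for k in trace.cycle]
    )
    inc = weights * utils * cycle.years_per_cycle * disc
    trace.qaly_inc = inc
    return float(inc.sum())


def evaluate_arm(
    arm: ArmSpec,
    cycle: CycleSpec,
    utility_mapping: str = "visit_end",
    half_cycle: bool = False,
) -> tuple[MarkovTrace, float, float]:
    """Run one arm end to end; returns (trace, total cost, total QALY)."""
    trace = run_trace(arm, cycle)
    cost = accrue_costs(trace, arm, cycle, half_cycle=half_cycle)
    qaly = accrue_qalys(trace, arm, cycle, utility_mapping, half_cycle=half_cycle)
    return trace, cost, qaly
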