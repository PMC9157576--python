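"""Deterministic (tornado) and probabilistic sensitivity analysis.

One-way analysis re-runs the full base case with one parameter (or grouped
parameter set) pushed to the low and high end of its fluctuation band —
±50% for costs, ±30% for utilities and for the Weibull transition
parameters — holding everything else at base.  A cost item carried
identically by both arms is treated as a single shared parameter, the
utility schedule of each arm as one grouped multiplier, and each arm's
(shape, scale) pair likewise; entries are ranked by the spread of the ICER.

Probabilistic analysis draws every parameter independently — utilities and
Weibull shape/scale from beta distributions, costs from gamma — with moments
matched to the fluctuation band: mean m, sd σ = m·f/d where d = 1.96 reads
the band as a central 95% interval (d = 2 is available).  Beta:
ν = m(1−m)/σ² − 1, α = mν, β = (1−m)ν.  Gamma: k = (d/f)², θ = m/k.  Each
Monte Carlo iteration evaluates the full two-arm model on a fresh parameter
set; a master seed spawns per-iteration substreams so results do not depend
on evaluation order.  The cost-effectiveness acceptability curve reports,
per willingness-to-pay value, the fraction of iterations with positive net
monetary benefit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd

from .cea_outcomes import nmb, run_cea
from .parameters_io import ArmSpec, ConfigError, ModelConfig, PSAConfig, UtilitySchedule

__all__ = [
    "ParamRange",
    "TornadoEntry",
    "PSAResult",
    "CEACPoint",
    "parameter_ranges",
    "one_way_dsa",
    "sample_parameters",
    "run_psa",
    "ceac",
    "DEFAULT_WTP_GRID",
]

#: Default willingness-to-pay grid for acceptability curves ($/QALY).
DEFAULT_WTP_GRID = np.arange(0.0, 60001.0, 500.0)


@dataclass(frozen=True)
class ParamRange:
    """A one-way sensitivity parameter (possibly a grouped multiplier).

    ``path`` is "<arm>:<name>" or "shared:<name>" for cost items carried
    identically by both arms; grouped entries ("<arm>:utilities",
    "<arm>:transition") vary all members by a common multiplier, so their
    base is 1.0.
    """

    path: str
    base: float
    low: float
    high: float
    family: str

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ValueError(f"{self.path}: need low <= base <= high")
        if self.family not in ("cost", "utility", "transition"):
            raise ValueError(f"{self.path}: unknown family '{self.family}'")


@dataclass(frozen=True)
class TornadoEntry:
    """ICER and net-monetary-benefit endpoints of one parameter's range.

    ``spread`` is the ICER range; ``nmb_spread`` the NMB range at the
    configured willingness-to-pay.  The NMB spread is the default influence
    ranking: when a perturbation pushes ΔE across zero the ICER changes sign
    and its spread becomes meaningless, while the NMB stays linear.
    """

    path: str
    family: str
    icer_low: float
    icer_high: float
    nmb_low: float = math.nan
    nmb_high: float = math.nan

    @property
    def spread(self) -> float:
        return abs(self.icer_high - self.icer_low)

    @property
    def nmb_spread(self) -> float:
        return abs(self.nmb_high - self.nmb_low)


def parameter_ranges(config: ModelConfig) -> list[ParamRange]:
    """Enumerate the one-way parameters with their fluctuation bands."""
    f_cost = config.dsa.cost
    f_util = config.dsa.utility
    f_trans = config.dsa.transition
    ranges: list[ParamRange] = []
    arm1, arm0 = config.arms
    shared = {
        c.name
        for c in arm1.costs
        for c0 in arm0.costs
        if c0.name == c.name and c0.amount == c.amount and c0.recurrence == c.recurrence
    }
    for name in sorted(shared):
        amount = arm1.cost_item(name).amount
        ranges.append(
            ParamRange(
                path=f"shared:{name}",
                base=amount,
                low=amount * (1 - f_cost),
                high=amount * (1 + f_cost),
                family="cost",
            )
        )
    for arm in config.arms:
        for c in arm.costs:
            if c.name in shared:
                continue
            ranges.append(
                ParamRange(
                    path=f"{arm.name}:{c.name}",
                    base=c.amount,
                    low=c.amount * (1 - f_cost),
                    high=c.amount * (1 + f_cost),
                    family="cost",
                )
            )
        ranges.append(
            ParamRange(
                path=f"{arm.name}:utilities",
                base=1.0,
                low=1 - f_util,
                high=1 + f_util,
                family="utility",
            )
        )
        ranges.append(
            ParamRange(
                path=f"{arm.name}:transition",
                base=1.0,
                low=1 - f_trans,
                high=1 + f_trans,
                family="transition",
            )
        )
    return ranges


def _with_value(config: ModelConfig, param: ParamRange, value: float) -> ModelConfig:
    """Return a config copy with ``param`` set to ``value`` (or multiplier)."""
    kind, _, name = param.path.partition(":")

    def set_cost(arm: ArmSpec) -> ArmSpec:
        costs = tuple(
            replace(c, amount=value) if c.name == name else c for c in arm.costs
        )
        return replace(arm, costs=costs)

    arms = list(config.arms)
    if param.family == "cost":
        for i, arm in enumerate(arms):
            if kind == "shared" or arm.name == kind:
                arms[i] = set_cost(arm)
    elif param.family == "utility":
        for i, arm in enumerate(arms):
            if arm.name == kind:
                # multiplier applied to the whole schedule; utilities cap at 1
                vals = tuple(min(1.0, v * value) for v in arm.utilities.values)
                arms[i] = replace(
                    arm,
                    utilities=UtilitySchedule(vals, arm.utilities.carry_forward),
                )
    else:  # transition: grouped multiplier on the (shape, scale) pair
        for i, arm in enumerate(arms):
            if arm.name == kind:
                surv = replace(
                    arm.survival,
                    shape=arm.survival.shape * value,
                    scale=arm.survival.scale * value,
                )
                arms[i] = replace(arm, survival=surv)
    return replace(config, arms=tuple(arms))


def one_way_dsa(
    config: ModelConfig, rank_by: str = "nmb", **conventions: Any
) -> list[TornadoEntry]:
    """Tornado entries, most influential parameter first.

    ``rank_by="nmb"`` (default) sorts by net-monetary-benefit spread at the
    configured WTP; ``rank_by="icer"`` sorts by raw ICER spread.
    """
    if rank_by not in ("nmb", "icer"):
        raise ValueError("rank_by must be 'nmb' or 'icer'")
    entries = []
    for param in parameter_ranges(config):
        res_lo = run_cea(_with_value(config, param, param.low), **conventions)
        res_hi = run_cea(_with_value(config, param, param.high), **conventions)
        entries.append(
            TornadoEntry(
                path=param.path,
                family=param.family,
                icer_low=res_lo.icer if res_lo.icer_defined else math.nan,
                icer_high=res_hi.icer if res_hi.icer_defined else math.nan,
                nmb_low=nmb(config.wtp, res_lo.delta_effect, res_lo.delta_cost),
                nmb_high=nmb(config.wtp, res_hi.delta_effect, res_hi.delta_cost),
            )
        )
    key = (lambda e: e.nmb_spread) if rank_by == "nmb" else (lambda e: e.spread)
    entries.sort(key=lambda e: (not math.isnan(key(e)), key(e)), reverse=True)
    return entries


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.path,
                "family": e.family,
                "icer_low": e.icer_low,
                "icer_high": e.icer_high,
                "spread": e.spread,
                "nmb_low": e.nmb_low,
                "nmb_high": e.nmb_high,
                "nmb_spread": e.nmb_spread,
            }
            for e in entries
        ]
    )


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


def _beta_draw(rng: np.random.Generator, mean: float, sd: float) -> float:
    if not 0.0 < mean < 1.0:
        raise ConfigError(
            f"beta sampling needs a mean in (0, 1), got {mean}; "
            "a parameter with mean >= 1 cannot use the beta family"
        )
    if sd == 0.0:
        return mean
    var = sd * sd
    if var >= mean * (1.0 - mean):
        raise ConfigError(f"beta sampling: sd {sd} too large for mean {mean}")
    nu = mean * (1.0 - mean) / var - 1.0
    return float(rng.beta(mean * nu, (1.0 - mean) * nu))


def _gamma_draw(rng: np.random.Generator, mean: float, f: float, d: float) -> float:
    if mean == 0.0 or f == 0.0:
        return mean
    k = (d / f) ** 2
    return float(rng.gamma(k, mean / k))


def sample_parameters(config: ModelConfig, rng: np.random.Generator) -> ModelConfig:
    """One joint parameter draw: beta utilities/transitions, gamma costs."""
    d = config.psa.sd_divisor
    f_cost, f_util, f_trans = config.dsa.cost, config.dsa.utility, config.dsa.transition
    arms = []
    for arm in config.arms:
        utils = tuple(
            min(1.0, _beta_draw(rng, v, v * f_util / d)) if f_util > 0 else v
            for v in arm.utilities.values
        )
        surv = replace(
            arm.survival,
            shape=_beta_draw(rng, arm.survival.shape, arm.survival.shape * f_trans / d)
            if f_trans > 0
            else arm.survival.shape,
            scale=_beta_draw(rng, arm.survival.scale, arm.survival.scale * f_trans / d)
            if f_trans > 0
            else arm.survival.scale,
        )
        costs = tuple(
            replace(c, amount=_gamma_draw(rng, c.amount, f_cost, d)) for c in arm.costs
        )
        arms.append(
            replace(
                arm,
                utilities=UtilitySchedule(utils, arm.utilities.carry_forward),
                survival=surv,
                costs=costs,
            )
        )
    return replace(config, arms=tuple(arms))


@dataclass
class PSAResult:
    """Per-iteration incremental (cost, effect) pairs plus the base case."""

    d_cost: np.ndarray
    d_effect: np.ndarray
    seed: int | None
    base_delta_cost: float
    base_delta_effect: float

    @property
    def n_iterations(self) -> int:
        return len(self.d_cost)

    @property
    def mean_delta_cost(self) -> float:
        return float(self.d_cost.mean())

    @property
    def mean_delta_effect(self) -> float:
        return float(self.d_effect.mean())

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iter": np.arange(self.n_iterations),
                "d_cost": self.d_cost,
                "d_qaly": self.d_effect,
            }
        )


@dataclass(frozen=True)
class CEACPoint:
    """Probability the intervention is cost-effective at one WTP value."""

    wtp: float
    probability: float


def run_psa(
    config: ModelConfig,
    psa: PSAConfig | None = None,
    seed: int | None = None,
    **conventions: Any,
) -> PSAResult:
    """Monte Carlo PSA: full model evaluations on sampled parameter sets."""
    psa = psa or config.psa
    master = seed if seed is not None else psa.seed
    streams = np.random.SeedSequence(master).spawn(psa.n_iterations)
    d_cost = np.empty(psa.n_iterations)
    d_effect = np.empty(psa.n_iterations)
    for i, ss in enumerate(streams):
        rng = np.random.Generator(np.random.PCG64(ss))
        sampled = sample_parameters(config, rng)
        res = run_cea(sampled, **conventions)
        d_cost[i] = res.delta_cost
        d_effect[i] = res.delta_effect
    base = run_cea(config, **conventions)
    return PSAResult(
        d_cost=d_cost,
        d_effect=d_effect,
        seed=master,
        base_delta_cost=base.delta_cost,
        base_delta_effect=base.delta_effect,
    )


def ceac(
    psa: PSAResult, wtp_grid: Iterable[float] = DEFAULT_WTP_GRID
) -> list[CEACPoint]:
    """Acceptability curve: P(NMB > 0) at each willingness-to-pay value."""
    points = []
    for wtp in wtp_grid:
        benefit = nmb(float(wtp), psa.d_effect, psa.d_cost)
        points.append(CEACPoint(wtp=float(wtp), probability=float((benefit > 0).mean())))
    return points


def ceac_frame(points: Sequence[CEACPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"wtp": p.wtp, "probability": p.probability} for p in points]
    )
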