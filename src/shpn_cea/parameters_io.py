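"""Domain types, configuration I/O and result writers.

The model compares two strategies for incurable gastrointestinal cancer
patients at nutritional risk — supplemental home parenteral nutrition (sHPN)
versus best-practice nutritional care — from the Chinese healthcare
perspective.  A configuration file (YAML) carries, per arm, the cost items
(US dollars, already converted from CNY; the exchange rate is metadata only),
a visit-wise utility schedule, and the Weibull survival parameters, together
with cycle settings (6-week cycles, 5-year horizon, 3% annual discount), the
willingness-to-pay threshold, and the sensitivity-analysis fluctuation
fractions.  The base-case parameter set ships with the package
(``load_fixture``) so the full analysis runs offline.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .survival import WeibullSurvival

log = logging.getLogger("shpn_cea")

__all__ = [
    "ConfigError",
    "CostItem",
    "UtilitySchedule",
    "CycleSpec",
    "ArmSpec",
    "PSAConfig",
    "DSAFluctuation",
    "ModelConfig",
    "EffectDelta",
    "METRIC_UNITS",
    "read_config",
    "write_config",
    "load_fixture",
    "apply_conventions",
    "write_results",
    "effect_deltas_to_frame",
    "effect_deltas_from_frame",
    "setup_logging",
]

#: Canonical units for each secondary effect metric. "h^-2" marks
#: height-normalized indices (kg per squared height in metres).
METRIC_UNITS: dict[str, str] = {
    "Qol": "utility",
    "BMI": "kg h^-2",
    "FFM": "kg",
    "FFMI": "kg h^-2",
    "Handgrip": "kg",
    "6MWT": "m",
}

DAYS_PER_YEAR = 365.25


class ConfigError(ValueError):
    """Configuration failed validation; the message names the offending key."""


@dataclass(frozen=True)
class CostItem:
    """A single cost component of an arm.

    ``recurrence`` is ``per_cycle`` (accrued every cycle while alive, within
    the applicability window) or ``once`` (accrued a single time, by default
    at model start).  ``treatment_linked`` marks items tied to the active
    nutritional intervention, so a finite treatment duration can stop them
    without touching background costs.
    """

    name: str
    amount: float
    recurrence: str = "per_cycle"
    applies_from_cycle: int = 0
    applies_through_cycle: int | None = None  # None = unbounded
    treatment_linked: bool = False

    def __post_init__(self) -> None:
        if self.recurrence not in ("per_cycle", "once"):
            raise ConfigError(f"cost '{self.name}': recurrence must be per_cycle|once")
        if not self.amount >= 0:
            raise ConfigError(f"cost '{self.name}': amount must be >= 0, got {self.amount}")
        if self.applies_from_cycle < 0:
            raise ConfigError(f"cost '{self.name}': applies_from_cycle must be >= 0")
        if (
            self.applies_through_cycle is not None
            and self.applies_through_cycle < self.applies_from_cycle
        ):
            raise ConfigError(
                f"cost '{self.name}': applies_from_cycle > applies_through_cycle"
            )


@dataclass(frozen=True)
class UtilitySchedule:
    """Five visit-wise utilities: baseline, then visits 2-5 (6-week spacing).

    With ``carry_forward`` the visit-5 utility applies to all later cycles.
    """

    values: tuple[float, float, float, float, float]
    carry_forward: bool = True

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", vals)
        if len(vals) != 5:
            raise ConfigError(f"utilities: exactly 5 values required, got {len(vals)}")
        for i, v in enumerate(vals):
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"utilities[{i}]: value {v} outside [0, 1]")

    @property
    def baseline(self) -> float:
        return self.values[0]

    def at_visit(self, visit: int) -> float:
        """Utility measured at visit 2..5 (visit 1 being baseline)."""
        if not 2 <= visit <= 5:
            raise ValueError(f"visit must be in 2..5, got {visit}")
        return self.values[visit - 1]

    def for_cycle(self, k: int, mapping: str = "visit_end") -> float:
        """Utility applied during cycle ``k`` (0-indexed).

        ``visit_end`` maps cycle k to the utility measured at the visit that
        closes it (visit k+2), carrying the last visit forward; ``visit_start``
        maps cycle k to the visit opening it (so cycle 0 uses baseline).
        """
        if mapping == "visit_end":
            idx = k + 1
        elif mapping == "visit_start":
            idx = k
        else:
            raise ValueError(f"unknown utility mapping '{mapping}'")
        if idx > 4 and not self.carry_forward:
            raise ValueError("cycle beyond schedule and carry_forward disabled")
        return self.values[min(idx, 4)]


@dataclass(frozen=True)
class CycleSpec:
    """Model timing: cycle length, horizon and annual discount rate.

    ``u`` optionally fixes the cycle length in Weibull model units; when
    ``None`` it is derived per arm as
    ``cycle_length_days / survival.time_unit_days``.
    """

    cycle_length_days: float = 42.0
    horizon_cycles: int = 43
    annual_discount_rate: float = 0.03
    u: float | None = None

    def __post_init__(self) -> None:
        if self.horizon_cycles < 1:
            raise ConfigError("cycle.horizon_cycles must be >= 1")
        if not 0.0 <= self.annual_discount_rate < 1.0:
            raise ConfigError("cycle.annual_discount_rate must be in [0, 1)")
        if not self.cycle_length_days > 0:
            raise ConfigError("cycle.cycle_length_days must be > 0")
        if self.u is not None and not self.u > 0:
            raise ConfigError("cycle.u must be > 0")

    @property
    def years_per_cycle(self) -> float:
        return self.cycle_length_days / DAYS_PER_YEAR

    def u_for(self, survival: WeibullSurvival) -> float:
        """Cycle length in the arm's Weibull model units."""
        return self.u if self.u is not None else self.cycle_length_days / survival.time_unit_days

    def discount_factor(self, k: int | Any) -> Any:
        """Discount at the start of cycle k: (1+r)^(-k * cycle_days / 365.25)."""
        import numpy as np

        years = np.asarray(k) * self.cycle_length_days / DAYS_PER_YEAR
        out = (1.0 + self.annual_discount_rate) ** (-years)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ArmSpec:
    """One strategy arm: survival model, cost items and utility schedule."""

    name: str
    survival: WeibullSurvival
    costs: tuple[CostItem, ...]
    utilities: UtilitySchedule

    def __post_init__(self) -> None:
        object.__setattr__(self, "costs", tuple(self.costs))
        names = [c.name for c in self.costs]
        if len(set(names)) != len(names):
            raise ConfigError(f"arm '{self.name}': duplicate cost item names")

    def cost_item(self, name: str) -> CostItem:
        for c in self.costs:
            if c.name == name:
                return c
        raise KeyError(f"arm '{self.name}' has no cost item '{name}'")


@dataclass(frozen=True)
class PSAConfig:
    """Probabilistic sensitivity analysis settings.

    ``interval_interpretation`` says how the deterministic fluctuation band
    m*(1±f) becomes a sampling standard deviation: ``central95`` reads it as
    a central 95% interval (sd = m*f/1.96), ``two_sd`` as a ±2-sd band.
    """

    n_iterations: int = 1000
    seed: int | None = None
    interval_interpretation: str = "central95"

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ConfigError("psa.n_iterations must be >= 1")
        if self.interval_interpretation not in ("central95", "two_sd"):
            raise ConfigError("psa.interval_interpretation must be central95|two_sd")

    @property
    def sd_divisor(self) -> float:
        return 1.96 if self.interval_interpretation == "central95" else 2.0


@dataclass(frozen=True)
class DSAFluctuation:
    """One-way/probabilistic fluctuation fractions by parameter family."""

    cost: float = 0.50
    utility: float = 0.30
    transition: float = 0.30

    def __post_init__(self) -> None:
        for fam in ("cost", "utility", "transition"):
            f = getattr(self, fam)
            if not 0.0 <= f < 1.0:
                raise ConfigError(f"dsa_fluctuation.{fam} must be in [0, 1)")

    def for_family(self, family: str) -> float:
        return getattr(self, family)


@dataclass(frozen=True)
class ModelConfig:
    """Complete model configuration: two arms plus analysis settings.

    ``arms[0]`` is the intervention, ``arms[1]`` the comparator.
    ``reference_results`` optionally carries published results used only for
    convention calibration and reporting, never by the engine.
    """

    arms: tuple[ArmSpec, ArmSpec]
    cycle: CycleSpec = field(default_factory=CycleSpec)
    wtp: float = 29307.0
    psa: PSAConfig = field(default_factory=PSAConfig)
    dsa: DSAFluctuation = field(default_factory=DSAFluctuation)
    currency: str = "USD"
    exchange_rate_cny_per_usd: float | None = None  # metadata only
    reference_results: Mapping[str, Any] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "arms", tuple(self.arms))
        if len(self.arms) != 2:
            raise ConfigError(f"arms: exactly 2 arms required, got {len(self.arms)}")
        if not self.wtp > 0:
            raise ConfigError("wtp must be > 0")

    @property
    def intervention(self) -> ArmSpec:
        return self.arms[0]

    @property
    def comparator(self) -> ArmSpec:
        return self.arms[1]


@dataclass(frozen=True)
class EffectDelta:
    """Per-visit change from baseline of one effect metric, for both arms.

    ``changes`` maps arm name to the four changes at visits 2-5, in the
    metric's canonical unit (utilities are dimensionless; BMI and FFMI in
    kg per height squared; FFM and handgrip in kg; 6-minute walk in m).
    """

    metric: str
    unit: str
    changes: Mapping[str, tuple[float, float, float, float]]

    def __post_init__(self) -> None:
        if self.metric in METRIC_UNITS and self.unit != METRIC_UNITS[self.metric]:
            raise ConfigError(
                f"metric '{self.metric}' must use unit '{METRIC_UNITS[self.metric]}'"
            )
        fixed = {arm: tuple(float(v) for v in vals) for arm, vals in self.changes.items()}
        for arm, vals in fixed.items():
            if len(vals) != 4:
                raise ConfigError(
                    f"effect '{self.metric}' arm '{arm}': need changes at visits 2-5"
                )
        object.__setattr__(self, "changes", fixed)

    def change_at(self, arm: str, visit: int) -> float:
        if not 2 <= visit <= 5:
            raise ValueError(f"visit must be in 2..5, got {visit}")
        return self.changes[arm][visit - 2]


# ---------------------------------------------------------------------------
# Configuration reading / writing
# ---------------------------------------------------------------------------


def _money(value: Any, key: str) -> float:
    try:
        amount = float(value)
    except (TypeError, ValueError):
        raise ConfigError(f"{key}: non-numeric amount {value!r}") from None
    # amounts are prices quoted to the cent; carried at full float precision
    if abs(amount * 100 - round(amount * 100)) > 1e-6:
        raise ConfigError(f"{key}: amount {value!r} has sub-cent precision")
    return amount


def _build_arm(raw: Mapping[str, Any], idx: int) -> ArmSpec:
    key = f"arms[{idx}]"
    try:
        name = raw["name"]
    except KeyError:
        raise ConfigError(f"{key}: missing 'name'") from None
    for section in ("survival", "utilities", "costs"):
        if section not in raw:
            raise ConfigError(f"{key} ('{name}'): missing '{section}'")
    s = raw["survival"]
    try:
        surv = WeibullSurvival(
            shape=float(s["shape"]),
            scale=float(s["scale"]),
            time_unit_days=float(s.get("time_unit_days", 42.0)),
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise ConfigError(f"{key}.survival: {exc}") from None
    u_raw = raw["utilities"]
    values = u_raw["values"] if isinstance(u_raw, Mapping) else u_raw
    try:
        utilities = UtilitySchedule(
            values=tuple(values),
            carry_forward=bool(u_raw.get("carry_forward", True))
            if isinstance(u_raw, Mapping)
            else True,
        )
    except ConfigError as exc:
        raise ConfigError(f"{key}.{exc}") from None
    costs = []
    for j, c in enumerate(raw["costs"]):
        ckey = f"{key}.costs[{j}]"
        if "name" not in c or "amount" not in c:
            raise ConfigError(f"{ckey}: cost items need 'name' and 'amount'")
        costs.append(
            CostItem(
                name=str(c["name"]),
                amount=_money(c["amount"], f"{ckey}.amount"),
                recurrence=str(c.get("recurrence", "per_cycle")),
                applies_from_cycle=int(c.get("applies_from_cycle", 0)),
                applies_through_cycle=(
                    None
                    if c.get("applies_through_cycle") in (None, "unbounded")
                    else int(c["applies_through_cycle"])
                ),
                treatment_linked=bool(c.get("treatment_linked", False)),
            )
        )
    return ArmSpec(name=name, survival=surv, costs=tuple(costs), utilities=utilities)


def config_from_mapping(raw: Mapping[str, Any]) -> ModelConfig:
    """Build and validate a :class:`ModelConfig` from parsed YAML/JSON."""
    if "arms" not in raw or raw["arms"] is None:
        raise ConfigError("missing 'arms'")
    arms_raw = raw["arms"]
    if len(arms_raw) != 2:
        raise ConfigError(f"arms: exactly 2 arms required, got {len(arms_raw)}")
    arms = tuple(_build_arm(a, i) for i, a in enumerate(arms_raw))
    cyc = raw.get("cycle", {}) or {}
    cycle = CycleSpec(
        cycle_length_days=float(cyc.get("cycle_length_days", 42.0)),
        horizon_cycles=int(cyc.get("horizon_cycles", 43)),
        annual_discount_rate=float(cyc.get("annual_discount_rate", 0.03)),
        u=None if cyc.get("u") is None else float(cyc["u"]),
    )
    psa_raw = raw.get("psa", {}) or {}
    psa = PSAConfig(
        n_iterations=int(psa_raw.get("n_iterations", 1000)),
        seed=None if psa_raw.get("seed") is None else int(psa_raw["seed"]),
        interval_interpretation=str(psa_raw.get("interval_interpretation", "central95")),
    )
    dsa_raw = raw.get("dsa_fluctuation", {}) or {}
    dsa = DSAFluctuation(
        cost=float(dsa_raw.get("cost", 0.50)),
        utility=float(dsa_raw.get("utility", 0.30)),
        transition=float(dsa_raw.get("transition", 0.30)),
    )
    return ModelConfig(
        arms=arms,  # type: ignore[arg-type]
        cycle=cycle,
        wtp=float(raw.get("wtp_per_qaly", 29307.0)),
        psa=psa,
        dsa=dsa,
        currency=str(raw.get("currency", "USD")),
        exchange_rate_cny_per_usd=(
            None
            if raw.get("exchange_rate_cny_per_usd") is None
            else float(raw["exchange_rate_cny_per_usd"])
        ),
        reference_results=raw.get("reference_results"),
    )


def read_config(path: str | Path) -> ModelConfig:
    """Read and validate a model configuration from a YAML file."""
    path = Path(path)
    with path.open() as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: top level must be a mapping")
    return config_from_mapping(raw)


def config_to_mapping(config: ModelConfig) -> dict[str, Any]:
    """Serialize a configuration back to plain mappings (YAML-ready)."""

    def arm_map(arm: ArmSpec) -> dict[str, Any]:
        return {
            "name": arm.name,
            "survival": {
                "shape": arm.survival.shape,
                "scale": arm.survival.scale,
                "time_unit_days": arm.survival.time_unit_days,
            },
            "utilities": {
                "values": list(arm.utilities.values),
                "carry_forward": arm.utilities.carry_forward,
            },
            "costs": [
                {
                    "name": c.name,
                    "amount": c.amount,
                    "recurrence": c.recurrence,
                    "applies_from_cycle": c.applies_from_cycle,
                    "applies_through_cycle": c.applies_through_cycle,
                    "treatment_linked": c.treatment_linked,
                }
                for c in arm.costs
            ],
        }

    out: dict[str, Any] = {
        "currency": config.currency,
        "exchange_rate_cny_per_usd": config.exchange_rate_cny_per_usd,
        "wtp_per_qaly": config.wtp,
        "cycle": {
            "cycle_length_days": config.cycle.cycle_length_days,
            "horizon_cycles": config.cycle.horizon_cycles,
            "annual_discount_rate": config.cycle.annual_discount_rate,
            "u": config.cycle.u,
        },
        "psa": {
            "n_iterations": config.psa.n_iterations,
            "seed": config.psa.seed,
            "interval_interpretation": config.psa.interval_interpretation,
        },
        "dsa_fluctuation": {
            "cost": config.dsa.cost,
            "utility": config.dsa.utility,
            "transition": config.dsa.transition,
        },
        "arms": [arm_map(a) for a in config.arms],
    }
    if config.reference_results is not None:
        out["reference_results"] = _plain(config.reference_results)
    return out


def _plain(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def write_config(config: ModelConfig, path: str | Path) -> Path:
    """Write a configuration to YAML; ``read_config`` round-trips it."""
    path = Path(path)
    with path.open("w") as fh:
        yaml.safe_dump(config_to_mapping(config), fh, sort_keys=False)
    return path


def load_fixture() -> ModelConfig:
    """The packaged base-case parameter set (sHPN vs best-practice care)."""
    text = resources.files("shpn_cea.data").joinpath("base_case.yaml").read_text()
    return config_from_mapping(yaml.safe_load(text))


def apply_conventions(
    config: ModelConfig,
    time_unit_days: float | None = None,
    treatment_cycles: int | None = None,
) -> ModelConfig:
    """Return a copy with alternative accrual conventions applied.

    ``time_unit_days`` re-interprets both arms' Weibull parameters in a
    different time unit; ``treatment_cycles`` stops treatment-linked
    per-cycle costs after that many cycles (e.g. 4 cycles = the 24-week
    treatment window).
    """
    arms = []
    for arm in config.arms:
        surv = arm.survival
        if time_unit_days is not None:
            surv = replace(surv, time_unit_days=time_unit_days)
        costs = arm.costs
        if treatment_cycles is not None:
            costs = tuple(
                replace(c, applies_through_cycle=treatment_cycles - 1)
                if c.treatment_linked and c.recurrence == "per_cycle"
                else c
                for c in costs
            )
        arms.append(replace(arm, survival=surv, costs=costs))
    return replace(config, arms=tuple(arms))


# ---------------------------------------------------------------------------
# Result writers
# ---------------------------------------------------------------------------


def effect_deltas_to_frame(deltas: Iterable[EffectDelta]) -> pd.DataFrame:
    """Tidy table (metric, arm, visit, change_from_baseline, unit)."""
    rows = []
    for d in deltas:
        for arm, vals in d.changes.items():
            for visit, change in zip(range(2, 6), vals):
                rows.append((d.metric, arm, visit, change, d.unit))
    return pd.DataFrame(
        rows, columns=["metric", "arm", "visit", "change_from_baseline", "unit"]
    )


def effect_deltas_from_frame(frame: pd.DataFrame) -> list[EffectDelta]:
    """Inverse of :func:`effect_deltas_to_frame`."""
    out = []
    for metric, grp in frame.groupby("metric", sort=False):
        unit = (
            str(grp["unit"].iloc[0])
            if "unit" in grp.columns
            else METRIC_UNITS.get(str(metric), "")
        )
        changes = {}
        for arm, sub in grp.groupby("arm", sort=False):
            sub = sub.sort_values("visit")
            if list(sub["visit"]) != [2, 3, 4, 5]:
                raise ConfigError(
                    f"effect '{metric}' arm '{arm}': visits must be exactly 2-5"
                )
            changes[str(arm)] = tuple(float(v) for v in sub["change_from_baseline"])
        out.append(EffectDelta(metric=str(metric), unit=unit, changes=changes))
    return out


def write_results(results: Any, path: str | Path) -> Path:
    """Write a result object to CSV (tables) or JSON (mappings).

    Accepts anything exposing ``frame() -> DataFrame`` (CEA, PSA, trace),
    a DataFrame, a list of tornado entries, or a plain mapping.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(results, Mapping):
        with path.open("w") as fh:
            json.dump(_plain(results), fh, indent=2)
        return path
    if isinstance(results, pd.DataFrame):
        results.to_csv(path, index=False)
        return path
    if hasattr(results, "frame"):
        results.frame().to_csv(path, index=False)
        return path
    if isinstance(results, (list, tuple)) and all(
        dataclasses.is_dataclass(r) for r in results
    ):
        frame = pd.DataFrame([dataclasses.asdict(r) for r in results])
        frame.to_csv(path, index=False)
        return path
    raise TypeError(f"cannot write results of type {type(results)!r}")


def setup_logging(verbose: bool = False) -> None:
    """Configure package logging for CLI use."""
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )
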