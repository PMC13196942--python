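"""Configuration and domain enumerations.

The simulated neighbourhood is parameterised entirely through
:class:`SimConfig`: population structure (households, household-size
distribution, dietary identity fractions), the social fabric (friend count,
status thresholds), the retail layer (supermarket count, service radius,
inventory sizing, replenishment cycle), the nightly dinner practice
(meal-selection strategy, meal variety, preference increment) and an optional
policy intervention.  Configs are immutable; derived experiments use
:func:`dataclasses.replace`.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "ProteinSource",
    "SupplyMode",
    "MealSelection",
    "InterventionKind",
    "StatusFilter",
    "InterventionSpec",
    "SimConfig",
    "ConfigError",
    "N_SOURCES",
]

N_SOURCES = 4


class ConfigError(ValueError):
    """Raised when a configuration value violates its documented domain."""


class ProteinSource(enum.IntEnum):
    """The four protein sources a dinner can feature.

    ``VEGETARIAN`` stands for dairy & eggs, ``VEGAN`` for plant-based
    proteins.  Every preference, inventory and sales vector is indexed by all
    four, in this order.
    """

    MEAT = 0
    FISH = 1
    VEGETARIAN = 2
    VEGAN = 3


class SupplyMode(enum.IntEnum):
    """How supermarket inventory behaves.

    INFINITE: stock never runs out and is never decremented.
    STATIC: restocks reset inventory to its initial composition.
    DYNAMIC: restock targets follow weekday-averaged sales plus unmet
    customer requests (a responsive, profit-seeking retailer).
    """

    INFINITE = 0
    STATIC = 1
    DYNAMIC = 2


class MealSelection(enum.IntEnum):
    """Household meal-negotiation strategy.

    RANDOM: the cook picks uniformly among the four sources.
    STATUS: the dinner guest with the highest social status (the cook
    included) dictates the meal via their dietary identity.
    MAJORITY: the modal dietary identity among the guests wins; ties are
    broken uniformly at random.
    """

    RANDOM = 0
    STATUS = 1
    MAJORITY = 2


class InterventionKind(enum.IntEnum):
    DIETARY_CHANGE = 0
    INVENTORY_CHANGE = 1


class StatusFilter(enum.IntEnum):
    """Which status stratum a dietary-change intervention targets."""

    LOW = 0     # status below the low threshold (default < 0.25)
    HIGH = 1    # status above the high threshold (default > 0.75)
    RANDOM = 2  # the whole population


def _parse_enum(cls, value, field_name):
    if isinstance(value, cls):
        return value
    if isinstance(value, str):
        try:
            return cls[value.strip().upper().replace("-", "_")]
        except KeyError:
            pass
    elif isinstance(value, int):
        try:
            return cls(value)
        except ValueError:
            pass
    raise ConfigError(
        f"{field_name}: {value!r} is not one of {[m.name for m in cls]}"
    )


@dataclass(frozen=True)
class InterventionSpec:
    """A scheduled policy intervention.

    ``DIETARY_CHANGE`` locks a sampled fraction of a status stratum onto a
    target diet for ``duration`` days; ``INVENTORY_CHANGE`` rewrites every
    supermarket's product range to a fixed plant share and freezes supply
    (static inventory) for the window.
    """

    kind: InterventionKind
    duration: int
    start_day: int = 730
    # dietary change only
    status_filter: StatusFilter | None = None
    target_diet: ProteinSource | None = None
    fraction_p: float | None = None
    # inventory change only
    plant_fraction: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "kind", _parse_enum(self.kind.__class__ if isinstance(self.kind, InterventionKind) else InterventionKind, self.kind, "intervention.kind"))
        if not 1 <= int(self.duration) <= 2920:
            raise ConfigError("intervention.duration: must be within [1, 2920] days")
        if self.start_day < 0:
            raise ConfigError("intervention.start_day: must be non-negative")
        if self.kind == InterventionKind.DIETARY_CHANGE:
            if self.status_filter is None or self.target_diet is None or self.fraction_p is None:
                raise ConfigError(
                    "dietary-change intervention requires status_filter, target_diet and fraction_p"
                )
            if self.plant_fraction is not None:
                raise ConfigError("dietary-change intervention must not set plant_fraction")
            object.__setattr__(self, "status_filter", _parse_enum(StatusFilter, self.status_filter, "intervention.status_filter"))
            object.__setattr__(self, "target_diet", _parse_enum(ProteinSource, self.target_diet, "intervention.target_diet"))
            if not 0.0 <= self.fraction_p <= 1.0:
                raise ConfigError("intervention.fraction_p: must be within [0, 1]")
        else:
            if self.plant_fraction is None:
                raise ConfigError("inventory-change intervention requires plant_fraction")
            if self.status_filter is not None or self.target_diet is not None or self.fraction_p is not None:
                raise ConfigError(
                    "inventory-change intervention must only set plant_fraction and duration"
                )
            if not 0.0 <= self.plant_fraction <= 0.95:
                raise ConfigError("intervention.plant_fraction: must be within [0, 0.95]")

    @property
    def end_day(self) -> int:
        return self.start_day + self.duration


_RANGE_FIELDS = {"plant_inventory_fraction_range", "business_orientation_range", "diet_fractions"}


@dataclass(frozen=True)
class SimConfig:
    """Global parameters of a simulation run.

    Defaults mirror Dutch neighbourhood statistics: 250 households of mean
    size 2.1, dietary identities 95.1% meat / 1.7% fish / 2.6% vegetarian /
    0.4% vegan, six supermarkets whose initial plant-protein volume lies in
    [0.35, 0.53], restocked every 4 days with a 10% safety margin.  One run
    covers ten years of daily steps (3650).
    """

    n_households: int = 250
    n_supermarkets: int = 6
    household_size_mean: float = 2.1
    # Dutch survey shares 95.1 / 1.7 / 2.6 / 0.4 % sum to 99.8; the default
    # keeps their ratios, renormalized so the vector is a distribution.
    diet_fractions: tuple[float, float, float, float] = (
        0.951 / 0.998,
        0.017 / 0.998,
        0.026 / 0.998,
        0.004 / 0.998,
    )
    n_friends: int = 3
    status_low_threshold: float = 0.25
    status_high_threshold: float = 0.75
    plant_inventory_fraction_range: tuple[float, float] = (0.35, 0.53)
    business_orientation_range: tuple[float, float] = (0.0, 2.0)
    service_radius: float = 40.0
    grid_size: int = 61
    safety_margin: float = 0.10
    replenishment_cycle: int = 4
    max_supermarket_visits: int = 2
    meal_variety: float = 0.3
    preference_increment: float = 0.01
    friend_invite_prob: float = 0.1
    years: int = 10
    days_per_year: int = 365
    supply_mode: SupplyMode = SupplyMode.DYNAMIC
    meal_selection: MealSelection = MealSelection.STATUS
    intervention: InterventionSpec | None = None
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "supply_mode", _parse_enum(SupplyMode, self.supply_mode, "supply_mode"))
        object.__setattr__(self, "meal_selection", _parse_enum(MealSelection, self.meal_selection, "meal_selection"))
        object.__setattr__(self, "diet_fractions", tuple(float(x) for x in self.diet_fractions))
        for name in ("plant_inventory_fraction_range", "business_orientation_range"):
            object.__setattr__(self, name, tuple(float(x) for x in getattr(self, name)))
        if isinstance(self.intervention, Mapping):
            object.__setattr__(self, "intervention", _intervention_from_dict(self.intervention))
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        def fail(fieldname, msg):
            raise ConfigError(f"{fieldname}: {msg}")

        if self.n_households < 1:
            fail("n_households", "must be at least 1")
        if self.n_supermarkets < 1:
            fail("n_supermarkets", "must be at least 1")
        if self.household_size_mean <= 1.0:
            fail("household_size_mean", "must exceed 1 (sizes are 1 + Poisson)")
        if len(self.diet_fractions) != N_SOURCES:
            fail("diet_fractions", "must have exactly four entries")
        if any(not 0.0 <= f <= 1.0 for f in self.diet_fractions):
            fail("diet_fractions", "entries must lie in [0, 1]")
        if abs(sum(self.diet_fractions) - 1.0) > 1e-9:
            fail("diet_fractions", "must sum to 1 within 1e-9")
        if self.n_friends < 0:
            fail("n_friends", "must be non-negative")
        if not 0.0 <= self.status_low_threshold <= self.status_high_threshold <= 1.0:
            fail("status_low_threshold/status_high_threshold", "need 0 <= low <= high <= 1")
        lo, hi = self.plant_inventory_fraction_range
        if not 0.0 <= lo <= hi <= 1.0:
            fail("plant_inventory_fraction_range", "must be an interval within [0, 1]")
        blo, bhi = self.business_orientation_range
        if not 0.0 <= blo <= bhi <= 2.0:
            fail("business_orientation_range", "must be an interval within [0, 2]")
        if not 20.0 <= self.service_radius <= 60.0:
            fail("service_radius", "must lie within [20, 60] grid cells")
        if self.grid_size < 1:
            fail("grid_size", "must be at least 1")
        if not 0.0 <= self.safety_margin <= 1.0:
            fail("safety_margin", "must lie in [0, 1]")
        if not 1 <= self.replenishment_cycle <= 12:
            fail("replenishment_cycle", "must lie within [1, 12] days")
        if not 1 <= self.max_supermarket_visits <= 8:
            fail("max_supermarket_visits", "must lie within [1, 8]")
        if not 0.0 < self.meal_variety <= 1.0:
            fail("meal_variety", "must lie in (0, 1]")
        if not 0.0 <= self.preference_increment <= 1.0:
            fail("preference_increment", "must lie in [0, 1]")
        if not 0.0 <= self.friend_invite_prob <= 1.0:
            fail("friend_invite_prob", "must lie in [0, 1]")
        if self.years < 1:
            fail("years", "must be at least 1")
        if self.days_per_year < 1:
            fail("days_per_year", "must be at least 1")
        if self.intervention is not None:
            if self.intervention.end_day > self.total_steps:
                fail(
                    "intervention",
                    f"start_day + duration ({self.intervention.end_day}) exceeds "
                    f"total steps ({self.total_steps})",
                )

    # -- derived ----------------------------------------------------------
    @property
    def total_steps(self) -> int:
        return self.years * self.days_per_year

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, enum.Enum):
                v = v.name
            elif isinstance(v, InterventionSpec):
                v = {
                    k: (x.name if isinstance(x, enum.Enum) else x)
                    for k, x in dataclasses.asdict(v).items()
                    if x is not None
                }
            elif isinstance(v, tuple):
                v = list(v)
            out[f.name] = v
        return out

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        kwargs = dict(data)
        if "intervention" in kwargs and kwargs["intervention"] is not None:
            kwargs["intervention"] = _intervention_from_dict(kwargs["intervention"])
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if data is None:
            data = {}
        if not isinstance(data, Mapping):
            raise ConfigError(f"{path}: expected a mapping of configuration keys")
        return cls.from_dict(data)


_STATUS_ALIASES = {
    ">0.75": StatusFilter.HIGH,
    "<0.25": StatusFilter.LOW,
    "high": StatusFilter.HIGH,
    "low": StatusFilter.LOW,
    "random": StatusFilter.RANDOM,
}


def _intervention_from_dict(data: Mapping[str, Any]) -> InterventionSpec:
    """Parse an intervention block.

    Two shapes are accepted: the explicit ``{"kind": ..., ...}`` form, and the
    interface-style blocks ``{"influencers": {"status", "diet", "p",
    "duration"[, "start_day"]}}`` / ``{"change_proteins": {"plant_fraction",
    "duration"[, "start_day"]}}``.
    """
    if isinstance(data, InterventionSpec):
        return data
    data = dict(data)
    if "influencers" in data or "change_proteins" in data:
        if len(data) != 1:
            raise ConfigError("intervention: give exactly one of 'influencers' or 'change_proteins'")
        if "influencers" in data:
            block = dict(data["influencers"])
            status = block.pop("status")
            if isinstance(status, str) and status.strip().lower() in _STATUS_ALIASES:
                status = _STATUS_ALIASES[status.strip().lower()]
            return InterventionSpec(
                kind=InterventionKind.DIETARY_CHANGE,
                status_filter=status,
                target_diet=block.pop("diet"),
                fraction_p=float(block.pop("p")),
                duration=int(block.pop("duration")),
                start_day=int(block.pop("start_day", 730)),
                **_require_empty(block, "influencers"),
            )
        block = dict(data["change_proteins"])
        return InterventionSpec(
            kind=InterventionKind.INVENTORY_CHANGE,
            plant_fraction=float(block.pop("plant_fraction")),
            duration=int(block.pop("duration")),
            start_day=int(block.pop("start_day", 730)),
            **_require_empty(block, "change_proteins"),
        )
    known = {f.name for f in dataclasses.fields(InterventionSpec)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown intervention keys: {sorted(unknown)}")
    data["kind"] = _parse_enum(InterventionKind, data.get("kind"), "intervention.kind")
    return InterventionSpec(**data)


def _require_empty(block: dict, name: str) -> dict:
    if block:
        raise ConfigError(f"unknown intervention keys under '{name}': {sorted(block)}")
    return {}
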