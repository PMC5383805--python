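"""Stochastic specification of the synthetic search log.

A :class:`GeneratorConfig` fully determines the log distribution: per
query-category Poisson baselines, a step-plus-geometric-decay event effect
switched on at the event day, isolated pre-event spike multipliers, the
query templates and clicked-domain weights used to materialise records, and
an event-agnostic control category whose multiplier is pinned at 1.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable

import yaml

from .errors import ConfigError

_WEIGHT_TOL = 1e-9


@dataclass(frozen=True)
class Spike:
    """An isolated one-day multiplicative surge for one category."""

    day: int
    category: str
    multiplier: float


@dataclass
class CategoryProfile:
    """Rate model and record content for one query category.

    ``baseline_rate`` is the expected queries/day (Poisson mean) before the
    event.  From the event day on, the rate is multiplied by
    ``1 + (event_multiplier - 1) * 2**(-(d - event_day)/decay_halflife_days)``:
    a step of size ``event_multiplier`` whose excess halves every
    ``decay_halflife_days`` days and relaxes back toward baseline.  An
    infinite half-life freezes the step (no decay).
    """

    name: str
    baseline_rate: float
    query_templates: list[str]
    domain_weights: dict[str, float]
    event_multiplier: float = 1.0
    decay_halflife_days: float = math.inf

    def validate(self) -> None:
        prefix = f"profile '{self.name}'"
        if not self.name:
            raise ConfigError("profile name must be nonempty")
        if self.baseline_rate < 0:
            raise ConfigError(f"{prefix}: baseline_rate must be >= 0")
        if self.event_multiplier < 0:
            raise ConfigError(f"{prefix}: event_multiplier must be >= 0")
        if not self.decay_halflife_days > 0:
            raise ConfigError(f"{prefix}: decay_halflife_days must be > 0")
        if not self.query_templates:
            raise ConfigError(f"{prefix}: query_templates must be nonempty")
        if not self.domain_weights:
            raise ConfigError(f"{prefix}: domain_weights must be nonempty")
        weights = list(self.domain_weights.values())
        if any(w < 0 for w in weights):
            raise ConfigError(f"{prefix}: domain_weights must be >= 0")
        if abs(sum(weights) - 1.0) > _WEIGHT_TOL:
            raise ConfigError(
                f"{prefix}: domain_weights must sum to 1 (got {sum(weights)!r})"
            )


@dataclass
class GeneratorConfig:
    """Full stochastic specification of a synthetic search log.

    Day indices are offsets from the event: with the default
    ``window_days=14`` the log covers days −14…+13, the before window is
    −14…−1 and the event day opens the after window.
    """

    profiles: list[CategoryProfile]
    control_profile: CategoryProfile
    spikes: list[Spike] = field(default_factory=list)
    event_day: int = 0
    window_days: int = 14
    seed: int = 0

    def validate(self) -> None:
        if self.window_days < 1:
            raise ConfigError("window_days must be >= 1")
        names = [p.name for p in self.profiles] + [self.control_profile.name]
        if len(set(names)) != len(names):
            raise ConfigError("profile names must be unique")
        for profile in self.all_profiles():
            profile.validate()
        if self.control_profile.event_multiplier != 1.0:
            raise ConfigError(
                "control_profile: event_multiplier is fixed at 1 for the control"
            )
        for spike in self.spikes:
            if spike.category not in names:
                raise ConfigError(f"spike references unknown category '{spike.category}'")
            if spike.multiplier < 0:
                raise ConfigError("spike multiplier must be >= 0")
            if not (self.first_day() <= spike.day <= self.last_day()):
                raise ConfigError(
                    f"spike day {spike.day} outside study window "
                    f"[{self.first_day()}, {self.last_day()}]"
                )

    # -- window geometry -------------------------------------------------
    def first_day(self) -> int:
        return self.event_day - self.window_days

    def last_day(self) -> int:
        return self.event_day + self.window_days - 1

    def days(self) -> range:
        return range(self.first_day(), self.last_day() + 1)

    def all_profiles(self) -> list[CategoryProfile]:
        return [*self.profiles, self.control_profile]

    # -- rate model ------------------------------------------------------
    def spike_multiplier(self, category: str, day: int) -> float:
        s = 1.0
        for spike in self.spikes:
            if spike.category == category and spike.day == day:
                s *= spike.multiplier
        return s

    def event_multiplier_on(self, profile: CategoryProfile, day: int) -> float:
        if day < self.event_day:
            return 1.0
        elapsed = day - self.event_day
        decay = 2.0 ** (-(elapsed / profile.decay_halflife_days))
        return 1.0 + (profile.event_multiplier - 1.0) * decay

    def rate(self, category: str, day: int) -> float:
        profile = self._profile(category)
        return (
            profile.baseline_rate
            * self.event_multiplier_on(profile, day)
            * self.spike_multiplier(category, day)
        )

    def _profile(self, category: str) -> CategoryProfile:
        for profile in self.all_profiles():
            if profile.name == category:
                return profile
        raise ConfigError(f"unknown category '{category}'")

    # -- (de)serialisation ----------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        for p in [*d["profiles"], d["control_profile"]]:
            if math.isinf(p["decay_halflife_days"]):
                p["decay_halflife_days"] = "inf"
        d["spikes"] = [list(astuple) for astuple in
                       ((s["day"], s["category"], s["multiplier"]) for s in d["spikes"])]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        def profile(p: dict) -> CategoryProfile:
            p = dict(p)
            hl = p.get("decay_halflife_days", math.inf)
            if isinstance(hl, str):
                hl = float(hl)
            p["decay_halflife_days"] = hl
            return CategoryProfile(**p)

        cfg = cls(
            profiles=[profile(p) for p in d["profiles"]],
            control_profile=profile(d["control_profile"]),
            spikes=[Spike(int(day), cat, float(mult))
                    for day, cat, mult in d.get("spikes", [])],
            event_day=int(d.get("event_day", 0)),
            window_days=int(d.get("window_days", 14)),
            seed=int(d.get("seed", 0)),
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def canonical_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))


def spikes_from_pairs(pairs: Iterable[tuple[int, str, float]]) -> list[Spike]:
    return [Spike(int(d), c, float(m)) for d, c, m in pairs]
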