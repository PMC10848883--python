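"""Monthly environmental schedules: temperature, productivity, spawning.

A schedule is a 12-month cycle of (temperature in Celsius, spectrum
productivity kappa, spawning permission) repeated over the full optimization
horizon. Constant environments, two-season environments, and the three
named tuna-lifestyle presets are provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .params import SpectrumParams

__all__ = [
    "MonthEnv",
    "EnvironmentSchedule",
    "constant_environment",
    "seasonal_environment",
    "lifestyle_preset",
    "LIFESTYLES",
]


@dataclass(frozen=True)
class MonthEnv:
    """Environmental conditions of a single month."""

    tau_c: float
    kappa: float
    spawn: bool


@dataclass(frozen=True)
class EnvironmentSchedule:
    """A 12-month periodic environment expanded over ``n_months``.

    Fields are per calendar month (length-12 tuples); month ``t`` of the
    horizon experiences entry ``t % 12``.
    """

    tau_by_month: tuple[float, ...]
    kappa_by_month: tuple[float, ...]
    spawn_by_month: tuple[bool, ...]
    n_months: int = 216

    def __post_init__(self) -> None:
        for name in ("tau_by_month", "kappa_by_month", "spawn_by_month"):
            value = tuple(getattr(self, name))
            object.__setattr__(self, name, value)
            if len(value) != 12:
                raise ValueError(f"{name} must have 12 entries, got {len(value)}")
        if any(k <= 0 for k in self.kappa_by_month):
            raise ValueError("kappa must be > 0 in every month")
        if not any(self.spawn_by_month):
            raise ValueError("at least one month must permit spawning")
        if self.n_months < 1:
            raise ValueError("n_months must be >= 1")

    @property
    def mean_kappa(self) -> float:
        """Yearly mean productivity (the scenario's comparable kappa)."""
        return float(np.mean(self.kappa_by_month))

    @property
    def mean_tau_c(self) -> float:
        """Yearly mean temperature in Celsius."""
        return float(np.mean(self.tau_by_month))

    def month(self, t: int) -> MonthEnv:
        """Conditions in month ``t`` (0-based) of the horizon."""
        m = t % 12
        return MonthEnv(
            tau_c=self.tau_by_month[m],
            kappa=self.kappa_by_month[m],
            spawn=bool(self.spawn_by_month[m]),
        )

    def months(self) -> Iterator[MonthEnv]:
        for t in range(self.n_months):
            yield self.month(t)

    def expand(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Full-horizon arrays (tau_c, kappa, spawn) of length ``n_months``."""
        idx = np.arange(self.n_months) % 12
        return (
            np.asarray(self.tau_by_month, dtype=float)[idx],
            np.asarray(self.kappa_by_month, dtype=float)[idx],
            np.asarray(self.spawn_by_month, dtype=bool)[idx],
        )

    def to_dict(self) -> dict:
        return {
            "tau_by_month": list(self.tau_by_month),
            "kappa_by_month": list(self.kappa_by_month),
            "spawn_by_month": [bool(x) for x in self.spawn_by_month],
            "n_months": self.n_months,
        }


def constant_environment(
    tau_c: float,
    kappa: float,
    spawn_all_year: bool = True,
    n_months: int = 216,
) -> EnvironmentSchedule:
    """An environment identical in every month.

    When ``spawn_all_year`` is false, spawning is restricted to the first
    three calendar months (a fixed warm window in an otherwise constant
    environment).
    """
    if not -50.0 < tau_c < 60.0:
        raise ValueError(f"tau_c={tau_c} outside a sane physical range (Celsius)")
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    spawn = (True,) * 12 if spawn_all_year else (True,) * 3 + (False,) * 9
    return EnvironmentSchedule(
        tau_by_month=(float(tau_c),) * 12,
        kappa_by_month=(float(kappa),) * 12,
        spawn_by_month=spawn,
        n_months=n_months,
    )


def seasonal_environment(
    winter_tau_c: float,
    summer_tau_c: float,
    winter_kappa: float,
    summer_kappa: float,
    warm_months: int = 3,
    spawn_in_warm_only: bool = True,
    warm_start_month: int = 0,
    n_months: int = 216,
) -> EnvironmentSchedule:
    """A two-season environment: a warm block and a cold remainder.

    ``warm_months`` consecutive months (starting at ``warm_start_month`` of the
    cycle) take the summer temperature and productivity; the rest take winter
    values. Spawning is restricted to the warm block when
    ``spawn_in_warm_only`` is true, otherwise permitted year-round. The warm
    block opens the cycle by default so natal cohorts appear at the start of
    the spawning season.
    """
    if not 1 <= warm_months <= 12:
        raise ValueError("warm_months must be in 1..12")
    if winter_kappa <= 0 or summer_kappa <= 0:
        raise ValueError("kappa must be > 0")
    warm = [(warm_start_month + i) % 12 for i in range(warm_months)]
    tau = [summer_tau_c if m in warm else winter_tau_c for m in range(12)]
    kap = [summer_kappa if m in warm else winter_kappa for m in range(12)]
    spawn = [True if m in warm else not spawn_in_warm_only for m in range(12)]
    if not spawn_in_warm_only:
        spawn = [True] * 12
    return EnvironmentSchedule(
        tau_by_month=tuple(tau),
        kappa_by_month=tuple(kap),
        spawn_by_month=tuple(spawn),
        n_months=n_months,
    )


#: Named environmental scenarios for the three tuna ecological lifestyles.
#: Each entry maps to (schedule kwargs builder, h). Winter productivity of the
#: temperate scenario is threefold the summer value and the warm (spawning)
#: season is 9 C warmer, with the 12-month mean kappa equal to 2.5.
LIFESTYLES = ("tropical_shallow", "tropical_deep", "temperate_deep")


def lifestyle_preset(
    name: str, n_months: int = 216
) -> tuple[EnvironmentSchedule, SpectrumParams]:
    """Environment and spectrum parameters for a named tuna lifestyle.

    * ``tropical_shallow`` -- constant 26.85 C, kappa = 0.1, h = 8 (e.g.
      frigate tuna above the thermocline).
    * ``tropical_deep`` -- constant 21.85 C, kappa = 1, h = 8 (e.g. yellowfin
      tuna foraging below the thermocline).
    * ``temperate_deep`` -- seasonal: 9 cold months at 11.85 C with threefold
      productivity (kappa = 3), 3 warm spawning months 9 C warmer with
      kappa = 1 (yearly mean 2.5), h = 12 (e.g. Atlantic bluefin tuna
      migrating between temperate foraging and tropical spawning grounds).
    """
    if name == "tropical_shallow":
        env = constant_environment(26.85, 0.1, spawn_all_year=True, n_months=n_months)
        sp = SpectrumParams(kappa=0.1, h=8.0)
    elif name == "tropical_deep":
        env = constant_environment(21.85, 1.0, spawn_all_year=True, n_months=n_months)
        sp = SpectrumParams(kappa=1.0, h=8.0)
    elif name == "temperate_deep":
        env = seasonal_environment(
            winter_tau_c=11.85,
            summer_tau_c=20.85,
            winter_kappa=3.0,
            summer_kappa=1.0,
            warm_months=3,
            spawn_in_warm_only=True,
            n_months=n_months,
        )
        sp = SpectrumParams(kappa=env.mean_kappa, h=12.0)
    else:
        raise ValueError(
            f"unknown lifestyle {name!r}; expected one of {LIFESTYLES}"
        )
    return env, sp
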