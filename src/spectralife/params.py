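"""Parameter containers for the size-spectrum life-history model.

Three groups of parameters govern the model:

* :class:`SpectrumParams` -- the ecosystem size spectrum, which sets both the
  prey field (income) and the predator field (mortality risk) of an individual
  as allometric functions of its body mass.
* :class:`MetabolicParams` -- mass- and temperature-scaling of maintenance
  costs, in the general form of the metabolic theory of ecology.
* :class:`BodyParams` -- the individual's bodyplan: length-mass conversion,
  tissue energy density, storage and reproductive-capacity limits, starvation
  threshold, and the lifetime horizon of the optimization.

Defaults are the tuna-calibrated values used throughout; every field can be
overridden.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

__all__ = [
    "SpectrumParams",
    "MetabolicParams",
    "BodyParams",
    "ModelParams",
    "KELVIN_OFFSET",
]

#: Additive offset between degrees Celsius and Kelvin.
KELVIN_OFFSET = 273.15


@dataclass(frozen=True)
class SpectrumParams:
    """Ecosystem size-spectrum parameters.

    The community abundance spectrum N(w) = kappa * w^lambda with lambda = -1
    yields, after integrating over the prey and predator fields of an
    individual of structural mass ``w`` (kg), the two allometries used here:

    * monthly prey biomass available: ``prey_coef * kappa * w**prey_exp`` (kg)
    * instantaneous predation mortality: ``mort_coef * h * w**mort_exp``

    ``prey_coef``/``prey_exp``/``mort_coef``/``mort_exp`` are the literature
    constants of those derivations (3, 0.05, 0.07, -0.25) and are exposed only
    so that the derivation can be stress-tested; ``kappa`` and ``h`` are the
    ecological degrees of freedom.

    The mortality allometry is calibrated on an annual timescale: survival
    over one month of the state dynamics is ``exp(-mu_p / mort_timescale_months)``.
    Interpreting the coefficient 0.07 as a purely monthly rate gives annual
    survival below 4% even for a 16 kg fish, which is incompatible with
    multi-year fish lifespans; the annual reading restores realistic
    magnitudes (monthly mu ~ 0.01 for a 400+ cm individual).
    """

    kappa: float = 1.0
    h: float = 8.0
    prey_coef: float = 3.0
    prey_exp: float = 0.05
    mort_coef: float = 0.07
    mort_exp: float = -0.25
    mort_timescale_months: float = 12.0

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError(f"kappa must be > 0, got {self.kappa}")
        if self.h <= 0:
            raise ValueError(f"h must be > 0, got {self.h}")
        if self.prey_coef <= 0 or self.mort_coef <= 0:
            raise ValueError("spectrum coefficients must be > 0")
        if self.mort_timescale_months <= 0:
            raise ValueError("mort_timescale_months must be > 0")


@dataclass(frozen=True)
class MetabolicParams:
    """Mass/temperature scaling of monthly maintenance costs.

    Monthly cost of an individual of mass ``w`` (kg) at absolute temperature
    ``tau`` (K) is ``c * w**theta * exp(-E / (kB * tau))`` joules.

    Notes
    -----
    ``kB`` defaults to the truncated value 1.3e-23 rather than the CODATA
    1.380649e-23 for consistency with the normalization constant ``c``, which
    was calibrated jointly with it; change both together or neither.
    """

    c: float = 5.0e16
    theta: float = 0.66
    E: float = 1.04e-19
    kB: float = 1.3e-23

    def __post_init__(self) -> None:
        for name in ("c", "theta", "E", "kB"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class BodyParams:
    """Bodyplan, storage and reproductive constraints, and horizon.

    Parameters
    ----------
    a
        Length-mass coefficient (kg cm^-3): structural mass w = a * l**3.
    rho
        Energy density of tissue (J kg^-1); converts between mass and energy.
    upsilon
        Starvation threshold as a fraction of structural-mass energy: survival
        of a month falls through 1/2 when stores equal ``upsilon * w * rho``.
    phi
        Maximum monthly reproductive output as a fraction of structural mass.
        ``phi = 0`` disables reproduction entirely.
    q
        Absolute steepness (J^-1) of the starvation sigmoid. ``None`` (the
        default) selects a scale-relative steepness in which the sigmoid rises
        from 0.01 to 0.99 over ``sigmoid_rel_width`` of the threshold energy,
        keeping the step equally sharp at every body size.
    sigmoid_rel_width
        Relative width of the starvation step (fraction of the threshold
        energy) when ``q`` is None.
    store_cap_frac
        Maximum lipid stores as a fraction of structural mass (energy basis).
    birth_length, birth_store_frac
        Natal state used by the cohort simulation: a ~10 cm age-0 juvenile
        recruit with stores at the starvation threshold. The monthly timestep
        and kg-scale allometries cannot resolve mm-scale larvae; recruiting at
        juvenile size keeps first-month predation mortality finite (a 1 cm
        "larva" would have a monthly mortality rate near 1 and no cohort
        would survive its first year at any parameter setting).
    max_length
        Hard ceiling on body length (cm); growth past it is truncated.
    t_max
        Optimization horizon in months (no reproduction is possible after it).
    """

    a: float = 1.0e-5
    rho: float = 4.2e6
    upsilon: float = 0.1
    phi: float = 0.2
    q: float | None = None
    sigmoid_rel_width: float = 0.01
    store_cap_frac: float = 0.6
    birth_length: float = 10.0
    birth_store_frac: float = 0.1
    max_length: float = 400.0
    t_max: int = 216

    def __post_init__(self) -> None:
        if self.a <= 0 or self.rho <= 0:
            raise ValueError("a and rho must be > 0")
        if not 0 < self.upsilon < self.store_cap_frac <= 1:
            raise ValueError(
                "require 0 < upsilon < store_cap_frac <= 1, got "
                f"upsilon={self.upsilon}, store_cap_frac={self.store_cap_frac}"
            )
        if not 0 <= self.phi <= 1:
            raise ValueError(f"phi must be in [0, 1], got {self.phi}")
        if self.q is not None and self.q <= 0:
            raise ValueError("q must be > 0 when given")
        if self.sigmoid_rel_width <= 0:
            raise ValueError("sigmoid_rel_width must be > 0")
        if not 0 < self.birth_length < self.max_length:
            raise ValueError("require 0 < birth_length < max_length")
        if not 0 <= self.birth_store_frac <= self.store_cap_frac:
            raise ValueError("birth_store_frac must lie in [0, store_cap_frac]")
        if self.t_max < 1:
            raise ValueError("t_max must be >= 1")


@dataclass(frozen=True)
class ModelParams:
    """Bundle of all parameter groups passed around the solver and simulator."""

    spectrum: SpectrumParams = field(default_factory=SpectrumParams)
    metabolism: MetabolicParams = field(default_factory=MetabolicParams)
    body: BodyParams = field(default_factory=BodyParams)

    def replace(self, **groups: Any) -> "ModelParams":
        """Return a copy with whole groups or individual fields replaced.

        Keyword arguments may be group names (``spectrum=...``) or any field
        name of a group (``kappa=2.0`` updates ``spectrum.kappa``).
        """
        spectrum, metabolism, body = self.spectrum, self.metabolism, self.body
        group_fields = {
            "spectrum": {f.name for f in dataclasses.fields(SpectrumParams)},
            "metabolism": {f.name for f in dataclasses.fields(MetabolicParams)},
            "body": {f.name for f in dataclasses.fields(BodyParams)},
        }
        for key, value in groups.items():
            if key == "spectrum":
                spectrum = value
            elif key == "metabolism":
                metabolism = value
            elif key == "body":
                body = value
            elif key in group_fields["spectrum"]:
                spectrum = dataclasses.replace(spectrum, **{key: value})
            elif key in group_fields["metabolism"]:
                metabolism = dataclasses.replace(metabolism, **{key: value})
            elif key in group_fields["body"]:
                body = dataclasses.replace(body, **{key: value})
            else:
                raise TypeError(f"unknown parameter {key!r}")
        return ModelParams(spectrum=spectrum, metabolism=metabolism, body=body)

    def to_dict(self) -> dict[str, dict[str, Any]]:
        return {
            "spectrum": dataclasses.asdict(self.spectrum),
            "metabolism": dataclasses.asdict(self.metabolism),
            "body": dataclasses.asdict(self.body),
        }

    @classmethod
    def from_dict(cls, d: dict[str, dict[str, Any]]) -> "ModelParams":
        return cls(
            spectrum=SpectrumParams(**d.get("spectrum", {})),
            metabolism=MetabolicParams(**d.get("metabolism", {})),
            body=BodyParams(**d.get("body", {})),
        )
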