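"""Allometric and physiological primitives.

Every relationship is a pure function of body state, temperature and a
parameter group, vectorized over numpy arrays. Masses are kg, lengths cm,
energies J, temperatures Kelvin (helpers convert from Celsius), rates per
month unless stated otherwise.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import expit

from .params import KELVIN_OFFSET, BodyParams, MetabolicParams, SpectrumParams

__all__ = [
    "celsius_to_kelvin",
    "kelvin_to_celsius",
    "prey_biomass",
    "predation_rate",
    "predation_survival",
    "monthly_predation_survival",
    "metabolic_cost",
    "mass_from_length",
    "length_from_mass",
    "stores_from_frac",
    "frac_from_stores",
    "max_reproduction",
    "starvation_steepness",
    "starvation_survival",
]

_ArrayLike = "np.typing.ArrayLike"


def celsius_to_kelvin(tau_c):
    """Convert degrees Celsius to Kelvin."""
    return np.asarray(tau_c, dtype=float) + KELVIN_OFFSET


def kelvin_to_celsius(tau_k):
    """Convert Kelvin to degrees Celsius."""
    return np.asarray(tau_k, dtype=float) - KELVIN_OFFSET


def _require_positive(x, name: str):
    arr = np.asarray(x, dtype=float)
    if np.any(arr <= 0) or np.any(~np.isfinite(arr)):
        raise ValueError(f"{name} must be positive and finite")
    return arr


def prey_biomass(w, sp: SpectrumParams):
    """Prey biomass (kg) available per month to an individual of mass ``w``.

    The integral of the prey field under a lambda = -1 community spectrum,
    ``prey_coef * kappa * w**prey_exp``: nearly mass-independent income that
    scales linearly with ecosystem productivity kappa.
    """
    w = _require_positive(w, "w")
    out = sp.prey_coef * sp.kappa * w**sp.prey_exp
    return out if out.ndim else float(out)


def predation_rate(w, sp: SpectrumParams):
    """Instantaneous predation mortality of an individual of mass ``w`` (kg).

    ``mort_coef * h * w**mort_exp``; declines with mass because ever fewer
    predators can swallow a growing individual. The rate accumulates over
    ``sp.mort_timescale_months`` months of exposure (see
    :func:`monthly_predation_survival`).
    """
    w = _require_positive(w, "w")
    out = sp.mort_coef * sp.h * w**sp.mort_exp
    return out if out.ndim else float(out)


def predation_survival(w, sp: SpectrumParams):
    """Probability of escaping predation over one full mortality timescale.

    ``exp(-mu_p(w))``; strictly increasing in mass, in (0, 1).
    """
    out = np.exp(-np.asarray(predation_rate(w, sp)))
    return out if out.ndim else float(out)


def monthly_predation_survival(w, sp: SpectrumParams):
    """Probability of escaping predation over a single month.

    ``exp(-mu_p(w) / mort_timescale_months)`` -- the per-step survival factor
    used by the state dynamics.
    """
    out = np.exp(-np.asarray(predation_rate(w, sp)) / sp.mort_timescale_months)
    return out if out.ndim else float(out)


def metabolic_cost(w, tau, mp: MetabolicParams):
    """Monthly maintenance cost (J) of mass ``w`` (kg) at temperature ``tau`` (K).

    ``c * w**theta * exp(-E / (kB * tau))``; increasing in both mass and
    temperature. ``tau`` below 200 K is rejected as an almost-certain
    Celsius/Kelvin mix-up -- use :func:`celsius_to_kelvin`.
    """
    w = _require_positive(w, "w")
    tau_arr = np.asarray(tau, dtype=float)
    if np.any(tau_arr < 200.0):
        raise ValueError(
            "tau looks like degrees Celsius (< 200 K); pass Kelvin, e.g. "
            "celsius_to_kelvin(16.85)"
        )
    out = mp.c * w**mp.theta * np.exp(-mp.E / (mp.kB * tau_arr))
    return out if out.ndim else float(out)


def mass_from_length(l, bp: BodyParams):
    """Structural mass (kg) of a fish of length ``l`` (cm): ``a * l**3``."""
    l = _require_positive(l, "l")
    out = bp.a * l**3
    return out if out.ndim else float(out)


def length_from_mass(w, bp: BodyParams):
    """Length (cm) of a fish of structural mass ``w`` (kg): ``(w / a)**(1/3)``."""
    w = _require_positive(w, "w")
    out = np.cbrt(w / bp.a)
    return out if out.ndim else float(out)


def stores_from_frac(frac, l, bp: BodyParams):
    """Lipid stores (J) at a store fraction of structural-mass energy."""
    out = np.asarray(frac, dtype=float) * (mass_from_length(l, bp) * bp.rho)
    return out if out.ndim else float(out)


def frac_from_stores(s, l, bp: BodyParams):
    """Store fraction of structural-mass energy for stores ``s`` (J)."""
    out = np.asarray(s, dtype=float) / (mass_from_length(l, bp) * bp.rho)
    return out if out.ndim else float(out)


def max_reproduction(w, bp: BodyParams):
    """Largest energy (J) spendable on reproduction in one month.

    Body-cavity constraint: gamete mass cannot exceed ``phi`` of structural
    mass, i.e. reproductive energy r*s must satisfy ``r*s <= phi * w * rho``.
    """
    w = _require_positive(w, "w")
    out = bp.phi * w * bp.rho
    return out if out.ndim else float(out)


def starvation_steepness(l, bp: BodyParams):
    """Steepness q (J^-1) of the starvation sigmoid at length ``l``.

    With the default scale-relative parameterization the sigmoid rises from
    0.01 to 0.99 over ``sigmoid_rel_width`` of the threshold energy
    ``upsilon * w(l) * rho``, so the step is equally sharp at all sizes.
    """
    if bp.q is not None:
        out = np.broadcast_to(np.asarray(bp.q, dtype=float), np.shape(l))
        return float(bp.q) if out.ndim == 0 else np.array(out)
    threshold = bp.upsilon * (mass_from_length(l, bp) * bp.rho)
    out = 2.0 * math.log(99.0) / (bp.sigmoid_rel_width * threshold)
    return out if np.ndim(out) else float(out)


def starvation_survival(s, l, bp: BodyParams):
    """Probability of avoiding starvation in the current month.

    Logistic in the surplus of stores over the critical level
    ``upsilon * w(l) * rho``: exactly 1/2 at the threshold, approaching a step
    function as q grows. ``s`` may be negative (an energy budget overdrawn by
    allocation), in which case survival is ~0.
    """
    l = _require_positive(l, "l")
    s = np.asarray(s, dtype=float)
    threshold = bp.upsilon * (mass_from_length(l, bp) * bp.rho)
    q = starvation_steepness(l, bp)
    out = expit(q * (s - threshold))
    return out if out.ndim else float(out)
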