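"""Forward cohort simulation under the optimal policy.

The forward pass is deterministic expected-cohort bookkeeping: growth and
allocation follow the optimal policy along a single state trajectory, while
mortality enters as a survivorship probability multiplied down each month
(not individual-level Monte Carlo). Reported reproduction-at-age comes in
two flavours: conditional on being alive, and discounted by the probability
of surviving to that age (the "expected" series used for fitness).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .allometry import frac_from_stores, mass_from_length, stores_from_frac
from .environment import EnvironmentSchedule
from .params import ModelParams
from .solver import PolicySolution, _repro_feasible, transition

__all__ = ["CohortTrajectory", "forward_simulate", "lifespan", "summarize"]

#: Expected-survival level below which the cohort is considered extinct.
LIFESPAN_THRESHOLD = 0.03


@dataclass(frozen=True)
class CohortTrajectory:
    """Monthly state, allocation and survivorship of a cohort from birth.

    All arrays have length ``t_max`` except ``survival_to_age`` (length
    ``t_max + 1``: entry t is the probability of being alive at the *start*
    of month t, starting at 1). ``repro_kg`` is conditional on survival;
    ``repro_kg_discounted`` multiplies in survival-to-age.
    """

    age_months: np.ndarray
    length_cm: np.ndarray
    stores_j: np.ndarray
    g: np.ndarray
    r: np.ndarray
    monthly_survival: np.ndarray
    survival_to_age: np.ndarray
    repro_kg: np.ndarray
    repro_kg_discounted: np.ndarray

    @property
    def t_max(self) -> int:
        return len(self.age_months)

    @property
    def max_length_attained(self) -> float:
        return float(self.length_cm.max())

    @property
    def lifespan_months(self) -> int:
        return lifespan(self)

    @property
    def lifetime_reproduction_kg(self) -> float:
        return float(self.repro_kg_discounted.sum())

    @property
    def age_first_reproduction_months(self) -> int | None:
        """First month with any allocation to reproduction, or None."""
        hits = np.flatnonzero(self.repro_kg > 0)
        return int(hits[0]) if len(hits) else None

    def to_frame(self) -> pd.DataFrame:
        """Tidy monthly table (one row per month of age)."""
        return pd.DataFrame(
            {
                "age_months": self.age_months,
                "length_cm": self.length_cm,
                "stores_j": self.stores_j,
                "g": self.g,
                "r": self.r,
                "monthly_survival": self.monthly_survival,
                "survival_to_age": self.survival_to_age[:-1],
                "repro_kg": self.repro_kg,
                "repro_kg_discounted": self.repro_kg_discounted,
            }
        )


def forward_simulate(
    policy: PolicySolution,
    env: EnvironmentSchedule | None = None,
    params: ModelParams | None = None,
    birth_length: float | None = None,
    birth_store_frac: float | None = None,
) -> CohortTrajectory:
    """Iterate a cohort forward from birth under the solved policy.

    The allocation at each monthly state is looked up by the same bilinear
    interpolation the solver uses for values, then re-projected to satisfy
    the allocation simplex, the spawning mask and the reproductive-capacity
    constraint before the transition is applied.
    """
    env = env or policy.env
    params = params or policy.params
    bp = params.body
    birth_length = bp.birth_length if birth_length is None else birth_length
    birth_store_frac = (
        bp.birth_store_frac if birth_store_frac is None else birth_store_frac
    )
    t_max = min(env.n_months, policy.t_max)

    l = float(birth_length)
    s = float(stores_from_frac(birth_store_frac, l, bp))

    length = np.empty(t_max)
    stores = np.empty(t_max)
    g_used = np.empty(t_max)
    r_used = np.empty(t_max)
    month_surv = np.empty(t_max)
    surv_to_age = np.empty(t_max + 1)
    repro_kg = np.empty(t_max)
    surv_to_age[0] = 1.0

    for t in range(t_max):
        me = env.month(t)
        frac = float(frac_from_stores(s, l, bp)) if s > 0 else 0.0
        g, r = policy.policy_at(l, frac, t)
        if not me.spawn:
            r = 0.0
        w = mass_from_length(l, bp)
        if s > 0 and not _repro_feasible(r * s, w, params):
            r = bp.phi * w * bp.rho / s
        res = transition(l, s, g, r, me, params)
        if not res.feasible:  # numerical corner: fall back to pure storage
            res = transition(l, s, 0.0, 0.0, me, params)
        length[t] = l
        stores[t] = s
        g_used[t] = g
        r_used[t] = r
        repro_kg[t] = res.repro / bp.rho
        month_surv[t] = res.survival
        surv_to_age[t + 1] = surv_to_age[t] * res.survival
        l, s = res.l_new, res.s_new

    return CohortTrajectory(
        age_months=np.arange(t_max),
        length_cm=length,
        stores_j=stores,
        g=g_used,
        r=r_used,
        monthly_survival=month_surv,
        survival_to_age=surv_to_age,
        repro_kg=repro_kg,
        repro_kg_discounted=repro_kg * surv_to_age[:-1],
    )


def lifespan(traj: CohortTrajectory, threshold: float = LIFESPAN_THRESHOLD) -> int:
    """Cohort lifespan: first age (months) at which expected survival has
    fallen to or below ``threshold``; the full horizon if it never does."""
    below = np.flatnonzero(traj.survival_to_age <= threshold)
    return int(below[0]) if len(below) else traj.t_max


def summarize(traj: CohortTrajectory) -> dict:
    """One-row scenario summary of a cohort trajectory."""
    first = traj.age_first_reproduction_months
    return {
        "max_length_cm": traj.max_length_attained,
        "lifespan_months": traj.lifespan_months,
        "lifespan_years": traj.lifespan_months / 12.0,
        "lifetime_repro_kg": traj.lifetime_reproduction_kg,
        "age_first_repro_months": np.nan if first is None else first,
        "survival_at_t_max": float(traj.survival_to_age[-1]),
    }
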