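"""Backward-induction solver for the optimal allocation policy.

Each month an individual of length ``l`` (cm) with lipid stores ``s`` (J)
splits its stores between growth (fraction ``g``), reproduction (``r``) and
carry-over (``1 - g - r``), while income from the prey field and maintenance
costs flow through the store. Fitness is expected lifetime reproductive
energy; the recursion

    V(l, s, t) = max over (g, r) of [ r*s + surv * V(l', s', t+1) ],

with V(., ., T) = 0 and ``surv`` the product of monthly predation and
starvation survival, is solved backward on a (length x store-fraction) grid,
evaluating off-grid successor states by bilinear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .environment import EnvironmentSchedule, MonthEnv
from .grid import StateGrid, allocation_lattice
from .params import KELVIN_OFFSET, ModelParams

__all__ = [
    "TransitionResult",
    "PolicySolution",
    "transition",
    "candidate_allocations",
    "backward_induction",
]

# relative slack on the reproductive-capacity constraint r*s <= phi*w*rho,
# so that an allocation meant to sit exactly on the cap is not excluded by
# floating-point rounding
_CAP_RTOL = 1e-12
# allocations within this relative distance of the maximum are treated as
# ties and resolved in favour of higher r, then higher g
_TIE_RTOL = 1e-12


class TransitionResult(NamedTuple):
    """Outcome of one month under a given allocation.

    ``feasible`` is False when the allocation violates the spawning mask or
    the reproductive-capacity constraint; state fields are NaN in that case.
    ``s_pre`` is the store level before flooring/capping -- the quantity the
    starvation sigmoid is evaluated on.
    """

    l_new: float
    s_new: float
    repro: float
    survival: float
    feasible: bool
    s_pre: float


def _step(l, s, g, r, tau_k, kappa, params: ModelParams):
    """Shared monthly state update, vectorized over any broadcastable shapes.

    Returns (l_new, s_pre, s_new, repro, survival). The same arithmetic path
    is used by the scalar :func:`transition` and the solver kernels so that
    on-grid successor states reproduce bit-identically.
    """
    sp, mp, bp = params.spectrum, params.metabolism, params.body
    w = bp.a * l**3
    income = bp.rho * (sp.prey_coef * kappa * w**sp.prey_exp)
    cost = mp.c * w**mp.theta * np.exp(-mp.E / (mp.kB * tau_k))
    l_new = np.minimum(np.cbrt(l**3 + (g * s) / (bp.a * bp.rho)), bp.max_length)
    w_new = bp.a * l_new**3
    repro = r * s
    s_pre = (1.0 - (g + r)) * s + (income - cost)
    s_new = np.clip(s_pre, 0.0, bp.store_cap_frac * (w_new * bp.rho))
    threshold = bp.upsilon * (w_new * bp.rho)
    if bp.q is not None:
        q = bp.q
    else:
        q = 2.0 * np.log(99.0) / (bp.sigmoid_rel_width * threshold)
    surv_starv = expit(q * (s_pre - threshold))
    mu = sp.mort_coef * sp.h * w**sp.mort_exp
    surv_pred = np.exp(-mu / sp.mort_timescale_months)
    survival = surv_pred * surv_starv
    return l_new, s_pre, s_new, repro, survival


def _repro_feasible(repro, w, params: ModelParams):
    """Body-cavity constraint r*s <= phi*w*rho, with relative slack."""
    cap = params.body.phi * w * params.body.rho
    return repro <= cap * (1.0 + _CAP_RTOL)


def candidate_allocations(l: float, s: float, params: ModelParams, n_alloc: int):
    """Allocation pairs considered at a state: the simplex lattice plus the
    state-exact reproductive-capacity pairs.

    The continuous model allows any r with r*s <= phi*w*rho; a fixed lattice
    cannot land on that cap, which makes the value function sawtooth in
    stores (a state with more stores can be unable to spawn the same absolute
    amount). Appending (0, r_cap) and (1 - r_cap, r_cap), with
    ``r_cap = min(phi*w*rho / s, 1)``, removes the artifact.
    """
    g_lat, r_lat = allocation_lattice(n_alloc)
    pairs = [(float(g), float(r)) for g, r in zip(g_lat, r_lat)]
    w = params.body.a * l**3
    cap = params.body.phi * w * params.body.rho
    r_cap = min(cap / s, 1.0) if s > 0 else 0.0
    pairs.append((0.0, r_cap))
    pairs.append((1.0 - r_cap, r_cap))
    return pairs


def transition(
    l: float,
    s: float,
    g: float,
    r: float,
    month_env: MonthEnv | tuple,
    params: ModelParams,
) -> TransitionResult:
    """Advance one individual one month under allocation ``(g, r)``.

    ``month_env`` is a :class:`~spectralife.environment.MonthEnv` or a
    ``(tau_c, kappa, spawn)`` tuple (temperature in Celsius). Raises
    ``ValueError`` for allocations outside the simplex (g, r >= 0,
    g + r <= 1) or non-positive state; returns an infeasible sentinel when
    the allocation violates the spawning mask or reproductive capacity.
    """
    if not isinstance(month_env, MonthEnv):
        month_env = MonthEnv(*month_env)
    if l <= 0:
        raise ValueError("l must be > 0")
    if s < 0:
        raise ValueError("s must be >= 0")
    if g < 0 or r < 0 or g + r > 1.0 + 1e-12:
        raise ValueError(f"allocation (g={g}, r={r}) outside the simplex")
    w = params.body.a * l**3
    repro = r * s
    if (r > 0 and not month_env.spawn) or not _repro_feasible(repro, w, params):
        return TransitionResult(
            float("nan"), float("nan"), float("nan"), float("nan"), False, float("nan")
        )
    tau_k = month_env.tau_c + KELVIN_OFFSET
    l_new, s_pre, s_new, repro, survival = _step(
        l, s, g, r, tau_k, month_env.kappa, params
    )
    return TransitionResult(
        float(l_new), float(s_new), float(repro), float(survival), True, float(s_pre)
    )


@dataclass(frozen=True)
class _MonthKernel:
    """Precomputed transition of every (allocation, state) pair for one
    distinct (tau, kappa, spawn) month type."""

    f00: np.ndarray  # (na, S) flat index of the lower interpolation corner
    sw00: np.ndarray  # (na, S) survival-folded bilinear corner weights
    sw01: np.ndarray
    sw10: np.ndarray
    sw11: np.ndarray
    reward: np.ndarray  # (na, S) current reproduction r*s; -inf if infeasible
    viable: np.ndarray  # (S,) states that can keep a non-negative budget


def _allocation_grids(grid: StateGrid, params: ModelParams):
    """Per-state (g, r) candidate arrays of shape (na + 2, nl, ns).

    First ``na`` rows are the fixed simplex lattice; the last two are the
    state-exact reproductive-capacity pairs (see
    :func:`candidate_allocations`).
    """
    bp = params.body
    nl, ns = grid.n_lengths, grid.n_stores
    g_lat, r_lat = grid.allocations()
    na = len(g_lat)
    l = grid.lengths[:, None]
    w_l = bp.a * l**3
    s_grid = grid.store_fracs[None, :] * (w_l * bp.rho)
    cap = bp.phi * w_l * bp.rho
    with np.errstate(divide="ignore", invalid="ignore"):
        r_cap = np.clip(np.where(s_grid > 0, cap / s_grid, 0.0), 0.0, 1.0)
    g = np.empty((na + 2, nl, ns))
    r = np.empty((na + 2, nl, ns))
    g[:na] = g_lat[:, None, None]
    r[:na] = r_lat[:, None, None]
    g[na], r[na] = 0.0, r_cap
    g[na + 1], r[na + 1] = 1.0 - r_cap, r_cap
    return g, r, s_grid, w_l


def _build_kernel(
    grid: StateGrid,
    params: ModelParams,
    env_month: MonthEnv,
    g: np.ndarray,
    r: np.ndarray,
    s_grid: np.ndarray,
    w_l: np.ndarray,
) -> _MonthKernel:
    bp = params.body
    lengths = grid.lengths
    fracs = grid.store_fracs
    nl, ns = grid.n_lengths, grid.n_stores

    l = lengths[:, None]  # (nl, 1)
    tau_k = env_month.tau_c + KELVIN_OFFSET

    l_new, s_pre, s_new, repro, survival = _step(
        l, s_grid, g, r, tau_k, env_month.kappa, params
    )
    l_new = np.broadcast_to(l_new, repro.shape)
    w_new = bp.a * l_new**3
    frac_new = s_new / (w_new * bp.rho)

    feas = _repro_feasible(repro, w_l, params)
    if not env_month.spawn:
        feas = feas & (r == 0.0)
    reward = np.where(feas, repro, -np.inf)

    il = np.clip(np.searchsorted(lengths, l_new, side="right") - 1, 0, nl - 2)
    wl = (l_new - lengths[il]) / (lengths[il + 1] - lengths[il])
    wl = np.clip(wl, 0.0, 1.0)
    isf = np.clip(np.searchsorted(fracs, frac_new, side="right") - 1, 0, ns - 2)
    ws = (frac_new - fracs[isf]) / (fracs[isf + 1] - fracs[isf])
    ws = np.clip(ws, 0.0, 1.0)
    f00 = (il * ns + isf).astype(np.intp)

    # a state is viable if income covers costs without dipping below an empty
    # store even when nothing is allocated; g = r = 0 is always in the lattice
    g_lat, r_lat = grid.allocations()
    zero = np.flatnonzero((g_lat == 0.0) & (r_lat == 0.0))[0]
    viable = (s_pre[zero] >= 0.0).reshape(-1)

    na = g.shape[0]
    flat = lambda a: np.ascontiguousarray(np.broadcast_to(a, reward.shape).reshape(na, -1))
    # fold the survival factor into the interpolation weights so that each
    # backward step is a pure gather-multiply-add
    return _MonthKernel(
        f00=flat(f00),
        sw00=flat(survival * ((1.0 - wl) * (1.0 - ws))),
        sw01=flat(survival * ((1.0 - wl) * ws)),
        sw10=flat(survival * (wl * (1.0 - ws))),
        sw11=flat(survival * (wl * ws)),
        reward=flat(reward),
        viable=viable,
    )


@dataclass(frozen=True)
class PolicySolution:
    """Optimal allocation policy and value function on the state grid.

    ``V`` has shape (t_max + 1, n_lengths, n_stores) with the terminal slice
    identically zero; ``g_star``/``r_star``/``feasible`` have shape
    (t_max, n_lengths, n_stores). ``V`` is in joules of expected lifetime
    reproductive energy; divide by ``params.body.rho`` for kg.
    """

    V: np.ndarray
    g_star: np.ndarray
    r_star: np.ndarray
    feasible: np.ndarray
    grid: StateGrid
    env: EnvironmentSchedule
    params: ModelParams

    @property
    def t_max(self) -> int:
        return self.g_star.shape[0]

    def _interp(self, arr2d: np.ndarray, l: float, frac: float) -> float:
        lengths, fracs = self.grid.lengths, self.grid.store_fracs
        l = float(np.clip(l, lengths[0], lengths[-1]))
        frac = float(np.clip(frac, fracs[0], fracs[-1]))
        il = int(np.clip(np.searchsorted(lengths, l, side="right") - 1, 0, len(lengths) - 2))
        isf = int(np.clip(np.searchsorted(fracs, frac, side="right") - 1, 0, len(fracs) - 2))
        wl = np.clip((l - lengths[il]) / (lengths[il + 1] - lengths[il]), 0.0, 1.0)
        ws = np.clip((frac - fracs[isf]) / (fracs[isf + 1] - fracs[isf]), 0.0, 1.0)
        a = arr2d
        return float(
            (1 - wl) * ((1 - ws) * a[il, isf] + ws * a[il, isf + 1])
            + wl * ((1 - ws) * a[il + 1, isf] + ws * a[il + 1, isf + 1])
        )

    def value_at(self, l: float, frac: float, t: int) -> float:
        """Bilinearly interpolated V (J) at an off-grid state."""
        return self._interp(self.V[t], l, frac)

    def policy_at(self, l: float, frac: float, t: int) -> tuple[float, float]:
        """Interpolated allocation (g, r) at an off-grid state.

        The interpolated pair is re-projected onto the simplex (g + r <= 1);
        the spawning mask and reproductive-capacity constraint are enforced by
        the caller, which knows the absolute store level.
        """
        g = self._interp(self.g_star[t], l, frac)
        r = self._interp(self.r_star[t], l, frac)
        g, r = max(g, 0.0), max(r, 0.0)
        tot = g + r
        if tot > 1.0:
            g, r = g / tot, r / tot
        return g, r

    def to_npz(self, path) -> None:
        """Save the solution to a compressed ``.npz`` array container.

        Stores the value function, policy arrays, grids and the environment /
        parameter configuration (as a JSON string); reload with
        :meth:`from_npz`.
        """
        import json

        np.savez_compressed(
            path,
            V=self.V,
            g_star=self.g_star,
            r_star=self.r_star,
            feasible=self.feasible,
            lengths=self.grid.lengths,
            store_fracs=self.grid.store_fracs,
            n_alloc=self.grid.n_alloc,
            env_json=json.dumps(self.env.to_dict()),
            params_json=json.dumps(self.params.to_dict()),
        )

    @classmethod
    def from_npz(cls, path) -> "PolicySolution":
        """Reload a solution saved by :meth:`to_npz`."""
        import json

        with np.load(path, allow_pickle=False) as data:
            grid = StateGrid(
                lengths=data["lengths"],
                store_fracs=data["store_fracs"],
                n_alloc=int(data["n_alloc"]),
            )
            env = EnvironmentSchedule(**json.loads(str(data["env_json"])))
            params = ModelParams.from_dict(json.loads(str(data["params_json"])))
            return cls(
                V=data["V"],
                g_star=data["g_star"],
                r_star=data["r_star"],
                feasible=data["feasible"],
                grid=grid,
                env=env,
                params=params,
            )

    def to_dataframe(self, months: Sequence[int] | None = None) -> pd.DataFrame:
        """Tabular export: one row per (length, store fraction, month)."""
        if months is None:
            months = range(self.t_max)
        ll, ff = np.meshgrid(self.grid.lengths, self.grid.store_fracs, indexing="ij")
        frames = []
        for t in months:
            frames.append(
                pd.DataFrame(
                    {
                        "month": t,
                        "length_cm": ll.ravel(),
                        "store_frac": ff.ravel(),
                        "V_joules": self.V[t].ravel(),
                        "g_star": self.g_star[t].ravel(),
                        "r_star": self.r_star[t].ravel(),
                        "feasible": self.feasible[t].ravel(),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def backward_induction(
    params: ModelParams,
    env: EnvironmentSchedule,
    grid: StateGrid | None = None,
) -> PolicySolution:
    """Solve the allocation problem by backward induction over the horizon.

    Transitions are precomputed once per distinct (temperature, productivity,
    spawning) month type -- schedules are 12-month periodic, so there are at
    most 12 -- and each backward step reduces to gathers of the successor
    value plus a maximization over the allocation lattice.
    """
    if grid is None:
        grid = StateGrid.default(params.body)
    t_max = env.n_months
    nl, ns = grid.n_lengths, grid.n_stores
    g_all, r_all, s_grid, w_l = _allocation_grids(grid, params)
    na = g_all.shape[0]
    g_flat = np.ascontiguousarray(g_all.reshape(na, -1))
    r_flat = np.ascontiguousarray(r_all.reshape(na, -1))

    month_envs = [env.month(t) for t in range(t_max)]
    kernels: dict[tuple, _MonthKernel] = {}
    for me in month_envs:
        key = (me.tau_c, me.kappa, me.spawn)
        if key not in kernels:
            kernels[key] = _build_kernel(grid, params, me, g_all, r_all, s_grid, w_l)

    V = np.zeros((t_max + 1, nl, ns))
    g_star = np.zeros((t_max, nl, ns))
    r_star = np.zeros((t_max, nl, ns))
    feasible = np.zeros((t_max, nl, ns), dtype=bool)

    v = np.zeros(nl * ns)
    for t in range(t_max - 1, -1, -1):
        me = month_envs[t]
        k = kernels[(me.tau_c, me.kappa, me.spawn)]
        f00 = k.f00
        # candidate value of every (allocation, state): reward now plus
        # survival-discounted interpolated continuation; -inf marks infeasible
        cand = k.reward + (
            k.sw00 * v[f00]
            + k.sw01 * v[f00 + 1]
            + k.sw10 * v[f00 + ns]
            + k.sw11 * v[f00 + ns + 1]
        )
        vmax = cand.max(axis=0)
        if not np.all(np.isfinite(vmax)):
            raise RuntimeError("non-finite value function: parameter pathology")
        best = (cand >= vmax - _TIE_RTOL * np.abs(vmax)).argmax(axis=0)
        v = np.where(k.viable, vmax, 0.0)
        cols = np.arange(nl * ns)
        V[t] = v.reshape(nl, ns)
        g_star[t] = np.where(k.viable, g_flat[best, cols], 0.0).reshape(nl, ns)
        r_star[t] = np.where(k.viable, r_flat[best, cols], 0.0).reshape(nl, ns)
        feasible[t] = k.viable.reshape(nl, ns)

    return PolicySolution(
        V=V,
        g_star=g_star,
        r_star=r_star,
        feasible=feasible,
        grid=grid,
        env=env,
        params=params,
    )
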