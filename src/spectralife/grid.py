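"""State-space discretization for the dynamic program.

The individual state is (body length l, lipid stores s). Stores are gridded
as a *fraction of structural-mass energy* (s / (w(l) * rho)) rather than in
absolute joules: the feasible store range scales with body size (the cap is
``store_cap_frac`` of structural mass), so a fractional grid keeps every node
meaningful at every length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import BodyParams

__all__ = ["StateGrid", "allocation_lattice"]


def allocation_lattice(n_alloc: int) -> tuple[np.ndarray, np.ndarray]:
    """Simplex lattice of (growth, reproduction) allocation fractions.

    All pairs ``(i, j) / (n_alloc - 1)`` with ``i + j <= n_alloc - 1``,
    including the vertices (0,0), (1,0), (0,1); ``n_alloc * (n_alloc + 1) / 2``
    pairs in total. Pairs are ordered by decreasing r then decreasing g, so a
    first-maximum argmax over the lattice implements the deterministic
    tie-break "prefer reproduction, then growth".
    """
    if n_alloc < 2:
        raise ValueError("n_alloc must be >= 2")
    step = n_alloc - 1
    pairs = [
        (i / step, j / step)
        for i in range(n_alloc)
        for j in range(n_alloc - i)
    ]
    pairs.sort(key=lambda gr: (-gr[1], -gr[0]))
    g = np.array([p[0] for p in pairs])
    r = np.array([p[1] for p in pairs])
    return g, r


@dataclass(frozen=True)
class StateGrid:
    """Discretization of the (length, store-fraction) state space.

    ``lengths`` (cm) and ``store_fracs`` (dimensionless, spanning 0 to the
    store cap) must be strictly increasing; off-grid states are handled by
    bilinear interpolation in this coordinate system.
    """

    lengths: np.ndarray
    store_fracs: np.ndarray
    n_alloc: int = 21

    def __post_init__(self) -> None:
        lengths = np.asarray(self.lengths, dtype=float)
        fracs = np.asarray(self.store_fracs, dtype=float)
        object.__setattr__(self, "lengths", lengths)
        object.__setattr__(self, "store_fracs", fracs)
        if lengths.ndim != 1 or len(lengths) < 2 or np.any(np.diff(lengths) <= 0):
            raise ValueError("lengths must be a strictly increasing 1-d grid")
        if fracs.ndim != 1 or len(fracs) < 2 or np.any(np.diff(fracs) <= 0):
            raise ValueError("store_fracs must be a strictly increasing 1-d grid")
        if fracs[0] != 0.0:
            raise ValueError("store_fracs must start at 0")
        if self.n_alloc < 2:
            raise ValueError("n_alloc must be >= 2")

    @property
    def n_lengths(self) -> int:
        return len(self.lengths)

    @property
    def n_stores(self) -> int:
        return len(self.store_fracs)

    @property
    def n_states(self) -> int:
        return self.n_lengths * self.n_stores

    def allocations(self) -> tuple[np.ndarray, np.ndarray]:
        return allocation_lattice(self.n_alloc)

    @classmethod
    def default(
        cls,
        body: BodyParams,
        n_lengths: int = 200,
        n_stores: int = 51,
        n_alloc: int = 21,
    ) -> "StateGrid":
        """Geometric length grid from birth to max length, uniform store grid.

        Geometric spacing in length resolves the fast early (small-body)
        growth phase; the store grid spans [0, store_cap_frac] uniformly.
        """
        lengths = np.geomspace(body.birth_length, body.max_length, n_lengths)
        lengths[0] = body.birth_length
        lengths[-1] = body.max_length
        store_fracs = np.linspace(0.0, body.store_cap_frac, n_stores)
        store_fracs[-1] = body.store_cap_frac
        return cls(lengths=lengths, store_fracs=store_fracs, n_alloc=n_alloc)

    def to_dict(self) -> dict:
        return {
            "n_lengths": self.n_lengths,
            "n_stores": self.n_stores,
            "n_alloc": self.n_alloc,
            "length_min": float(self.lengths[0]),
            "length_max": float(self.lengths[-1]),
            "store_frac_max": float(self.store_fracs[-1]),
        }
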