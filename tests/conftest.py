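"""Shared helpers: an exhaustive-enumeration oracle for the dynamic program
and exactly-gridded toy instances to compare it against."""

import numpy as np

from spectralife import StateGrid, candidate_allocations, transition
from spectralife.allometry import frac_from_stores, stores_from_frac


def oracle_value(l, frac, t, env, params, n_alloc):
    """Brute-force value of a state: max over every allocation sequence.

    Independent of the grid solver: recursion over the continuous state, the
    max over allocation sequences of current reward plus survival-discounted
    continuation. Exponential in the remaining horizon; only for toys.
    """
    if t == env.n_months:
        return 0.0
    bp = params.body
    me = env.month(t)
    s = stores_from_frac(frac, l, bp)
    best = None
    for g, r in candidate_allocations(l, s, params, n_alloc):
        res = transition(l, s, float(g), float(r), me, params)
        if not res.feasible:
            continue
        frac_new = frac_from_stores(res.s_new, res.l_new, bp)
        cont = oracle_value(res.l_new, frac_new, t + 1, env, params, n_alloc)
        v = res.repro + res.survival * cont
        if best is None or v > best:
            best = v
    return best


def reachable_closure(l0, frac0, env, params, n_alloc):
    """All (length, store fraction) states visited at decision months."""
    bp = params.body
    seen = set()

    def visit(l, frac, t):
        if t == env.n_months:
            return
        seen.add((l, frac))
        s = stores_from_frac(frac, l, bp)
        me = env.month(t)
        for g, r in candidate_allocations(l, s, params, n_alloc):
            res = transition(l, s, float(g), float(r), me, params)
            if res.feasible:
                visit(res.l_new, frac_from_stores(res.s_new, res.l_new, bp), t + 1)

    visit(l0, frac0, 0)
    return seen


def exact_toy_grid(starts, env, params, n_alloc):
    """A state grid whose nodes contain every reachable toy state, so that
    all successor states of reachable nodes land exactly on grid nodes and
    bilinear interpolation introduces no error."""
    states = set()
    for l0, f0 in starts:
        states |= reachable_closure(l0, f0, env, params, n_alloc)
    lengths = np.array(sorted({l for l, _ in states}))
    fracs = np.array(sorted({f for _, f in states} | {0.0}))
    return StateGrid(lengths=lengths, store_fracs=fracs, n_alloc=n_alloc)
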