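"""The individual-based model proper.

One discrete generation consists of four stages applied in order:

1. migration decision (``decide_step``) — every individual compares its
   heritable threshold T with the winter survival it can expect locally as a
   resident, density included, and becomes a MIGRANT or a RESIDENT;
2. winter survival (``winter_step``) — migrants survive with the constant
   probability ``s_m``, residents with the location- and density-dependent
   probability of the resident survival gradient;
3. dispersal (``disperse_step``) — each survivor relocates with probability
   ``d`` to a cell within Chebyshev distance ``delta``, with reflecting
   ("bouncing") landscape borders;
4. reproduction (``reproduce_step``) — each survivor produces a brood drawn
   from U{0..max_brood}, corrected for location and density; offspring inherit
   the mother's threshold subject to mutation, and all parents die.

Random-stream contract
----------------------
For a fixed seed the stages consume the generator in a fixed order and with
fixed draw shapes (decision tie-breaks: n uniforms; winter: n uniforms;
dispersal: n uniforms for the move mask, then offset indices for the movers
plus re-draws for reflected duplicates of the origin; reproduction: n brood
integers, n rounding uniforms, one uniform per offspring for the mutation
mask, then one per mutant). Trajectories are therefore bit-reproducible for a
given (params, seed).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .params import SimParams
from .population import MIGRANT, RESIDENT, UNDECIDED, Population

__all__ = [
    "nominal_resident_survival",
    "resident_survival",
    "reproduction_factor",
    "decide_migration",
    "decide_step",
    "winter_step",
    "disperse_step",
    "reproduce_step",
    "run_generation",
]


def _maybe_scalar(a: np.ndarray, scalar_in: bool):
    return float(a) if scalar_in else a


def nominal_resident_survival(x, surv_delta: float = 0.0, x_max: int = 100):
    """Density-free resident winter survival at column ``x``.

    The survival gradient rises linearly from 0.01 at the polar edge (x=1) to
    1.0 at the equatorial edge (x=100); an environmental-change scenario may
    shift it additively by ``surv_delta``. The result is clamped to [0, 1].
    """
    scalar = np.isscalar(x)
    x = np.asarray(x)
    if np.any((x < 1) | (x > x_max)):
        raise ValueError(f"column index outside landscape [1, {x_max}]")
    return _maybe_scalar(np.clip(0.01 * x + surv_delta, 0.0, 1.0), scalar)


def resident_survival(x, n_res, params: SimParams):
    """Resident winter survival: nominal gradient times the density factor.

    ``s_r = clamp( clamp(0.01 x + surv_delta, 0, 1) * (1 - (1 - c_dens_s) * n_res / K), 0, 1 )``

    Non-increasing in the resident count ``n_res``; zero at and beyond a
    resident density of ``K / (1 - c_dens_s)`` (2.5 K at the default 0.6).
    """
    scalar = np.isscalar(x) and np.isscalar(n_res)
    n_res = np.asarray(n_res)
    if np.any(n_res < 0):
        raise ValueError("resident count must be non-negative")
    nominal = nominal_resident_survival(x, params.surv_delta, params.x_max)
    dens = 1.0 - (1.0 - params.c_dens_s) * n_res / params.K
    return _maybe_scalar(np.clip(nominal * dens, 0.0, 1.0), scalar)


def reproduction_factor(x, n_total, params: SimParams):
    """Total reproduction correction factor c_tot in [0, 1].

    Product of the location term (declining linearly from 1 at x=1 to
    ``1 - (1 - c_loc_r)`` at x=100, i.e. 0.8 at the default) and the density
    term ``1 - (1 - c_dens_r) N / K``, clamped to [0, 1].
    """
    scalar = np.isscalar(x) and np.isscalar(n_total)
    x = np.asarray(x)
    n_total = np.asarray(n_total)
    if np.any((x < 1) | (x > params.x_max)):
        raise ValueError(f"column index outside landscape [1, {params.x_max}]")
    if np.any(n_total < 0):
        raise ValueError("patch count must be non-negative")
    loc = 1.0 - 0.01 * x * (1.0 - params.c_loc_r)
    dens = 1.0 - (1.0 - params.c_dens_r) * n_total / params.K
    return _maybe_scalar(np.clip(loc * dens, 0.0, 1.0), scalar)


def decide_migration(patch_thresholds, x: int, params: SimParams, rng) -> np.ndarray:
    """Self-consistent migration decision for one patch.

    Individuals anticipate the winter survival they would have as residents,
    density included. With thresholds sorted ascending, the realized resident
    count n* is the largest n whose n-th smallest threshold does not exceed
    ``resident_survival(x, n)``; because the sorted thresholds increase while
    survival decreases in n, the n* smallest-threshold individuals are exactly
    the self-consistent resident set. Ties at the marginal threshold are
    broken uniformly at random. An individual migrates iff its expected
    survival is strictly below its threshold.

    Returns a boolean array aligned with ``patch_thresholds``; True marks a
    resident.
    """
    T = np.asarray(patch_thresholds, dtype=np.float64)
    if np.any((T < 0) | (T > 1)):
        raise ValueError("thresholds must lie in [0, 1]")
    n = T.size
    if n == 0:
        return np.zeros(0, dtype=bool)
    tie = rng.random(n)
    order = np.lexsort((tie, T))
    ranks = np.arange(1, n + 1)
    s_r = resident_survival(np.full(n, x), ranks, params)
    resident_sorted = T[order] <= s_r
    out = np.empty(n, dtype=bool)
    out[order] = resident_sorted
    return out


def decide_step(pop: Population, params: SimParams, rng) -> Population:
    """Assign phenotypes to every individual (vectorized over all patches).

    Implements the same sorted fixed point as :func:`decide_migration`, one
    lexsort over the whole landscape keyed by (patch, threshold, tie-break).
    """
    n = pop.size
    new = pop.copy()
    if n == 0:
        return new
    tie = rng.random(n)
    patch = pop.patch_index(params.y_max)
    order = np.lexsort((tie, pop.T, patch))
    p_s = patch[order]
    # 1-based rank of each individual within its patch, in sorted order
    pos = np.arange(n, dtype=np.int64)
    is_start = np.empty(n, dtype=bool)
    is_start[0] = True
    is_start[1:] = p_s[1:] != p_s[:-1]
    group_start = np.maximum.accumulate(np.where(is_start, pos, 0))
    rank = pos - group_start + 1
    s_r = resident_survival(pop.x[order], rank, params)
    resident_sorted = pop.T[order] <= s_r
    phen = np.empty(n, dtype=np.int8)
    phen[order] = np.where(resident_sorted, RESIDENT, MIGRANT)
    new.phenotype = phen
    return new


def winter_step(pop: Population, params: SimParams, rng) -> Population:
    """Winter survival; requires phenotypes assigned for this generation.

    Each migrant survives independently with probability ``s_m``; each
    resident with ``resident_survival(x, n_res)`` where ``n_res`` is its
    patch's resident count fixed at decision time.
    """
    n = pop.size
    if n == 0:
        return pop.copy()
    if np.any(pop.phenotype == UNDECIDED):
        raise ValueError("winter_step requires phenotypes assigned (run decide_step)")
    patch = pop.patch_index(params.y_max)
    n_patches = params.n_patches
    n_res = np.bincount(patch[pop.phenotype == RESIDENT], minlength=n_patches)
    p_surv = np.where(
        pop.phenotype == MIGRANT,
        params.s_m,
        resident_survival(pop.x, n_res[patch], params),
    )
    keep = rng.random(n) < p_surv
    return pop.take(keep)


@lru_cache(maxsize=None)
def _dispersal_offsets(delta: int) -> np.ndarray:
    """All (dx, dy) with Chebyshev distance in [1, delta]; shape (M, 2)."""
    r = np.arange(-delta, delta + 1)
    dx, dy = np.meshgrid(r, r, indexing="ij")
    off = np.column_stack([dx.ravel(), dy.ravel()])
    return off[(off[:, 0] != 0) | (off[:, 1] != 0)]


def reflect_coordinate(c, c_max: int):
    """Fold a coordinate back into [1, c_max] by reflection at both edges.

    Implements bouncing borders: a step past the edge is mirrored back
    (e.g. x = 0 -> 2, x = c_max + 1 -> c_max - 1), repeatedly if needed.
    """
    c = np.asarray(c)
    if c_max == 1:
        return np.ones_like(c)
    period = 2 * (c_max - 1)
    r = np.mod(c - 1, period)
    return 1 + np.minimum(r, period - r)


def disperse_step(pop: Population, params: SimParams, rng) -> Population:
    """Relocate each survivor with probability ``d``.

    Destinations are uniform over the cells within Chebyshev distance
    ``delta`` of the origin, excluding the origin; out-of-range coordinates
    bounce off the landscape edges, and draws whose reflected destination
    coincides with the origin cell are re-drawn. The individual count is
    conserved.
    """
    n = pop.size
    new = pop.copy()
    if n == 0:
        return new
    move = rng.random(n) < params.d
    idx = np.flatnonzero(move)
    if idx.size == 0:
        return new
    if params.x_max == 1 and params.y_max == 1:
        return new  # single-cell landscape: nowhere to go
    off = _dispersal_offsets(params.delta)
    x0, y0 = new.x[idx], new.y[idx]
    nx = np.empty_like(x0)
    ny = np.empty_like(y0)
    todo = np.arange(idx.size)
    while todo.size:
        pick = off[rng.integers(0, off.shape[0], todo.size)]
        nx[todo] = reflect_coordinate(x0[todo] + pick[:, 0], params.x_max)
        ny[todo] = reflect_coordinate(y0[todo] + pick[:, 1], params.y_max)
        todo = todo[(nx[todo] == x0[todo]) & (ny[todo] == y0[todo])]
    new.x[idx] = nx
    new.y[idx] = ny
    return new


def reproduce_step(pop: Population, params: SimParams, rng) -> Population:
    """Reproduction with inheritance and mutation; all parents die.

    Each parent draws a brood size No ~ U{0..max_brood}; the corrected
    offspring number is ``R = No * c_tot(x, N)`` — times
    ``migr_repro_factor`` for migrant parents — where N is the patch total
    after dispersal. R is realized by stochastic rounding
    (floor(R) + Bernoulli(frac(R)), preserving its expectation). Offspring
    inherit the mother's threshold and mutate with probability ``m`` to a
    uniform draw on [0, 1]; their phenotype is UNDECIDED until the next
    decision stage. Returns the next generation.
    """
    g_next = pop.generation + 1
    n = pop.size
    if n == 0:
        return Population.empty(generation=g_next)
    patch = pop.patch_index(params.y_max)
    n_tot = np.bincount(patch, minlength=params.n_patches)
    c_tot = reproduction_factor(pop.x, n_tot[patch], params)
    brood = rng.integers(0, params.max_brood + 1, n)
    R = brood * c_tot
    if params.migr_repro_factor != 1.0:
        R = np.where(pop.phenotype == MIGRANT, R * params.migr_repro_factor, R)
    k = np.floor(R)
    k += rng.random(n) < (R - k)
    k = k.astype(np.int64)
    reps = np.repeat(np.arange(n), k)
    T_off = pop.T[reps]
    n_off = T_off.size
    mut = rng.random(n_off) < params.m
    n_mut = int(mut.sum())
    if n_mut:
        T_off = T_off.copy()
        T_off[mut] = rng.random(n_mut)
    return Population(
        x=pop.x[reps],
        y=pop.y[reps],
        T=T_off,
        phenotype=np.full(n_off, UNDECIDED, dtype=np.int8),
        generation=g_next,
    )


def run_generation(pop: Population, params: SimParams, rng) -> Population:
    """Advance one full generation: decide, winter, disperse, reproduce."""
    pop = decide_step(pop, params, rng)
    pop = winter_step(pop, params, rng)
    pop = disperse_step(pop, params, rng)
    return reproduce_step(pop, params, rng)
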