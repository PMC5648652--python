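"""Unit and property tests for the generation-cycle model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from partmig import (
    MIGRANT,
    RESIDENT,
    UNDECIDED,
    Population,
    SimParams,
    decide_migration,
    decide_step,
    disperse_step,
    nominal_resident_survival,
    reproduce_step,
    reproduction_factor,
    resident_survival,
    run_generation,
    winter_step,
)
from partmig.model import reflect_coordinate


def make_patch(n, x, T, phen=None, y=1):
    """Population with n individuals in a single patch."""
    phen = np.full(n, UNDECIDED if phen is None else phen, dtype=np.int8)
    return Population(
        x=np.full(n, x), y=np.full(n, y), T=np.asarray(T, float) * np.ones(n), phenotype=phen
    )


# ---------------------------------------------------------------- gradients


@pytest.mark.parametrize(
    "x,surv_delta,expected",
    [
        (1, 0.0, 0.01),
        (100, 0.0, 1.0),
        (10, -0.2, 0.0),  # clamped at zero
        (70, -0.2, 0.5),
        (90, 0.2, 1.0),  # clamped at one
    ],
)
def test_nominal_resident_survival_gradient(x, surv_delta, expected):
    assert nominal_resident_survival(x, surv_delta) == pytest.approx(expected)


def test_nominal_survival_rejects_off_landscape():
    with pytest.raises(ValueError):
        nominal_resident_survival(0)
    with pytest.raises(ValueError):
        nominal_resident_survival(101)


@pytest.mark.parametrize(
    "x,n_res,expected",
    [
        (100, 250, 0.0),  # density 2.5 K extinguishes survival
        (50, 0, 0.5),
        (80, 100, 0.48),
    ],
)
def test_resident_survival_examples(params, x, n_res, expected):
    assert resident_survival(x, n_res, params) == pytest.approx(expected)


def test_resident_survival_monotonicity(params):
    dens = np.arange(0, 400)
    for x in (1, 37, 100):
        s = resident_survival(np.full(dens.size, x), dens, params)
        assert np.all(np.diff(s) <= 0)
    xs = np.arange(1, 101)
    s = resident_survival(xs, np.zeros(100), params)
    assert np.all(np.diff(s) >= 0)


def test_resident_survival_rejects_negative_count(params):
    with pytest.raises(ValueError):
        resident_survival(10, -1, params)


@pytest.mark.parametrize(
    "x,n_total,expected",
    [
        (100, 0, 0.8),  # pure location term at the equatorial edge
        (1, 100, 0.3992),
        (1, 0, 0.998),
    ],
)
def test_reproduction_factor_examples(params, x, n_total, expected):
    assert reproduction_factor(x, n_total, params) == pytest.approx(expected)


def test_reproduction_factor_monotone_in_x_and_density(params):
    xs = np.arange(1, 101)
    f = reproduction_factor(xs, np.zeros(100), params)
    assert np.all(np.diff(f) <= 0)
    dens = np.arange(0, 300)
    f = reproduction_factor(np.full(dens.size, 40), dens, params)
    assert np.all(np.diff(f) <= 0)


# ---------------------------------------------------------- migration decision


def brute_force_residents(T, x, params):
    """Independent oracle: largest n whose n-th smallest threshold is still
    compatible with the resident survival realized at n residents."""
    T_sorted = np.sort(np.asarray(T, float))
    n_star = 0
    for n in range(1, T_sorted.size + 1):
        if T_sorted[n - 1] <= resident_survival(x, n, params):
            n_star = n
    return n_star, T_sorted[:n_star]


def test_single_zero_threshold_is_always_resident(params, rng):
    for x in (1, 50, 100):
        assert decide_migration([0.0], x, params, rng).all()


def test_decision_fixed_point_uniform_thresholds(params, rng):
    res = decide_migration(np.full(100, 0.6), 80, params, rng)
    assert res.sum() == 62


def test_zero_density_phenotype_switch(params):
    # a T=0.5 individual facing zero density: migrant below the column where
    # the nominal survival gradient reaches 0.5, resident from there on
    s = resident_survival(np.arange(1, 101), np.zeros(100), params)
    resident = s >= 0.5
    assert not resident[:49].any() and resident[49:].all()  # switch at x=50
    shifted = SimParams(surv_delta=-0.2)
    s2 = resident_survival(np.arange(1, 101), np.zeros(100), shifted)
    resident2 = s2 >= 0.5
    assert int(np.argmax(resident2) + 1) == 70  # migratory region ends at x=70


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    n=st.integers(0, 200),
    x=st.integers(1, 100),
    seed=st.integers(0, 2**31 - 1),
)
def test_decision_matches_brute_force_enumeration(n, x, seed):
    params = SimParams()
    rng = np.random.default_rng(seed)
    T = rng.random(n)
    res = decide_migration(T, x, params, np.random.default_rng(seed + 1))
    n_star, resident_T = brute_force_residents(T, x, params)
    assert res.sum() == n_star
    np.testing.assert_allclose(np.sort(T[res]), resident_T)
    # self-consistency: every resident tolerates the realized density
    if n_star:
        assert np.max(T[res]) <= resident_survival(x, n_star, params)


def test_decision_ties_at_marginal_threshold_randomized(params):
    # 100 identical thresholds at x=80 -> 62 residents; which individuals
    # stay must vary across seeds
    T = np.full(100, 0.6)
    picks = [
        frozenset(np.flatnonzero(decide_migration(T, 80, params, np.random.default_rng(s))))
        for s in range(5)
    ]
    assert len(set(picks)) > 1
    assert all(len(p) == 62 for p in picks)


def test_decide_step_matches_per_patch_decision(params):
    # vectorized landscape-wide decision == per-patch decide_migration
    rng = np.random.default_rng(3)
    n = 600
    pop = Population(
        x=rng.integers(1, params.x_max + 1, n),
        y=rng.integers(1, params.y_max + 1, n),
        T=rng.random(n),
        phenotype=np.zeros(n, dtype=np.int8),
    )
    decided = decide_step(pop, params, np.random.default_rng(0))
    patch = pop.patch_index(params.y_max)
    for p in np.unique(patch):
        sel = patch == p
        x = int(pop.x[sel][0])
        n_star, resident_T = brute_force_residents(pop.T[sel], x, params)
        got = decided.phenotype[sel] == RESIDENT
        assert got.sum() == n_star
        np.testing.assert_allclose(np.sort(pop.T[sel][got]), resident_T)


# ----------------------------------------------------------------- winter


def test_winter_requires_decided_phenotypes(params, rng):
    with pytest.raises(ValueError):
        winter_step(make_patch(5, 10, 0.5), params, rng)


def test_migrant_survival_is_binomial_sm(params):
    pop = make_patch(10_000, 10, 0.9, phen=MIGRANT)
    survivors = winter_step(pop, params, np.random.default_rng(0))
    # Binomial(10000, 0.5): observed count within 5 sigma of the mean
    assert abs(survivors.size - 5000) < 5 * np.sqrt(10_000 * 0.25)


def test_resident_at_2p5K_density_never_survives(params):
    pop = make_patch(250, 100, 0.9, phen=RESIDENT)
    assert winter_step(pop, params, np.random.default_rng(0)).size == 0


def test_sole_resident_at_equatorial_edge_almost_always_survives(params):
    # survival probability 1 * (1 - 0.4/100) = 0.996
    outcomes = [
        winter_step(make_patch(1, 100, 0.3, phen=RESIDENT), params,
                    np.random.default_rng(s)).size
        for s in range(2000)
    ]
    assert np.mean(outcomes) == pytest.approx(0.996, abs=0.01)


# --------------------------------------------------------------- dispersal


def test_reflect_coordinate_matches_single_bounce():
    # low edge: x' = 2 - x; high edge: x' = 2*x_max - x
    for c in (-1, 0):
        assert reflect_coordinate(c, 100) == 2 - c
    for c in (101, 102):
        assert reflect_coordinate(c, 100) == 200 - c
    assert np.array_equal(reflect_coordinate(np.arange(1, 101), 100), np.arange(1, 101))


def brute_force_destinations(x0, y0, params):
    """All reachable cells: reflect every Chebyshev-<=delta offset, drop the
    cells that fold back onto the origin."""
    dests = set()
    for dx in range(-params.delta, params.delta + 1):
        for dy in range(-params.delta, params.delta + 1):
            if dx == 0 and dy == 0:
                continue
            nx, ny = x0 + dx, y0 + dy
            while not 1 <= nx <= params.x_max:
                nx = 2 - nx if nx < 1 else 2 * params.x_max - nx
            while not 1 <= ny <= params.y_max:
                ny = 2 - ny if ny < 1 else 2 * params.y_max - ny
            if (nx, ny) != (x0, y0):
                dests.add((nx, ny))
    return dests


@pytest.mark.parametrize("origin", [(50, 13), (1, 1), (100, 25), (2, 1)])
def test_dispersal_destination_set_matches_reflection_oracle(params, origin):
    x0, y0 = origin
    pop = make_patch(4000, x0, 0.5, phen=RESIDENT, y=y0)
    moved = disperse_step(pop, params.replace(d=1.0), np.random.default_rng(0))
    got = set(zip(moved.x.tolist(), moved.y.tolist()))
    assert got == brute_force_destinations(x0, y0, params)


def test_interior_cell_has_24_candidate_destinations(params):
    assert len(brute_force_destinations(50, 13, params)) == 24


def test_no_dispersal_when_d_zero(params, rng):
    pop = make_patch(500, 42, 0.5, phen=RESIDENT, y=7)
    out = disperse_step(pop, params.replace(d=0.0), rng)
    assert np.array_equal(out.x, pop.x) and np.array_equal(out.y, pop.y)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1), d=st.floats(0, 1), delta=st.integers(1, 5))
def test_dispersal_conserves_individuals_within_bounds(seed, d, delta):
    params = SimParams(x_max=20, y_max=6, d=d, delta=delta)
    rng = np.random.default_rng(seed)
    n = 300
    pop = Population(
        x=rng.integers(1, 21, n), y=rng.integers(1, 7, n),
        T=rng.random(n), phenotype=np.full(n, RESIDENT, np.int8),
    )
    out = disperse_step(pop, params, rng)
    assert out.size == n
    assert out.x.min() >= 1 and out.x.max() <= 20
    assert out.y.min() >= 1 and out.y.max() <= 6
    np.testing.assert_array_equal(np.sort(out.T), np.sort(pop.T))


# ------------------------------------------------------------- reproduction


def test_zero_reproduction_factor_gives_no_offspring(params, rng):
    # N = 2.5 K drives the density term of c_tot to zero
    pop = make_patch(250, 40, 0.5, phen=RESIDENT)
    off = reproduce_step(pop, params, rng)
    assert off.size == 0 and off.generation == 1


@pytest.mark.parametrize("phen,factor", [(RESIDENT, 1.0), (MIGRANT, 0.8)])
def test_expected_offspring_is_3_ctot(params, phen, factor):
    # E[No] = 3 for U{0..6}; lone parent at x=60 has c_tot = 0.92 * 0.994
    p = params.replace(migr_repro_factor=0.8)
    c_tot = reproduction_factor(60, 1, p)
    counts = [
        reproduce_step(make_patch(1, 60, 0.5, phen=phen), p, np.random.default_rng(s)).size
        for s in range(4000)
    ]
    assert np.mean(counts) == pytest.approx(3 * c_tot * factor, rel=0.05)


def test_offspring_inherit_then_mutate(params):
    pop = make_patch(2000, 1, 0.37, phen=RESIDENT, y=1)
    pop.y = np.random.default_rng(5).integers(1, 26, 2000).astype(np.int32)
    # m=0: inheritance is exact
    off = reproduce_step(pop, params.replace(m=0.0), np.random.default_rng(1))
    assert off.size > 0 and np.all(off.T == 0.37)
    assert np.all(off.phenotype == UNDECIDED)
    # m=0.2: mutant fraction near m, mutants uniform draws != mother's value
    off = reproduce_step(pop, params.replace(m=0.2), np.random.default_rng(1))
    frac = np.mean(off.T != 0.37)
    assert frac == pytest.approx(0.2, abs=0.03)


def test_parents_die(params, rng):
    pop = make_patch(50, 60, 0.5, phen=RESIDENT)
    off = reproduce_step(pop, params, rng)
    assert off.generation == pop.generation + 1
    # all offspring born in the parents' patch
    assert np.all(off.x == 60)


# ----------------------------------------------------------- full generation


def naive_generation(pop, params, rng):
    """Straight-line per-individual reimplementation of the four stages,
    consuming the generator with the documented draw shapes."""
    n = pop.size
    x = int(pop.x[0])
    # decision: sorted fixed point with random tie-break
    tie = rng.random(n)
    order = sorted(range(n), key=lambda i: (pop.T[i], tie[i]))
    n_star = 0
    for k in range(1, n + 1):
        if pop.T[order[k - 1]] <= resident_survival(x, k, params):
            n_star = k
    phen = np.full(n, MIGRANT, np.int8)
    for i in order[:n_star]:
        phen[i] = RESIDENT
    # winter
    u = rng.random(n)
    keep = [
        i
        for i in range(n)
        if u[i] < (params.s_m if phen[i] == MIGRANT
                   else resident_survival(x, n_star, params))
    ]
    # dispersal (d = 0: the move-mask draw still happens)
    u = rng.random(len(keep))
    assert not np.any(u < params.d)
    # reproduction
    m = len(keep)
    brood = rng.integers(0, params.max_brood + 1, m)
    u = rng.random(m)
    xs, ys, Ts = [], [], []
    for j, i in enumerate(keep):
        c = reproduction_factor(x, m, params)
        R = brood[j] * c * (params.migr_repro_factor if phen[i] == MIGRANT else 1.0)
        k = int(np.floor(R)) + (u[j] < R - np.floor(R))
        xs += [pop.x[i]] * k
        ys += [pop.y[i]] * k
        Ts += [pop.T[i]] * k
    assert not np.any(rng.random(len(Ts)) < params.m)  # m = 0
    return Population(
        x=np.array(xs, np.int32), y=np.array(ys, np.int32), T=np.array(Ts),
        phenotype=np.full(len(Ts), UNDECIDED, np.int8), generation=pop.generation + 1,
    )


def test_one_patch_generation_matches_hand_stepped_oracle():
    params = SimParams(d=0.0, m=0.0, K=30)
    rng = np.random.default_rng(77)
    pop = Population(
        x=np.full(40, 60), y=np.full(40, 3), T=rng.random(40),
        phenotype=np.zeros(40, np.int8),
    )
    got = run_generation(pop.copy(), params, np.random.default_rng(11))
    want = naive_generation(pop, params, np.random.default_rng(11))
    assert got.generation == want.generation
    np.testing.assert_array_equal(got.x, want.x)
    np.testing.assert_array_equal(got.y, want.y)
    np.testing.assert_array_equal(got.T, want.T)


def test_empty_landscape_stays_empty(params, rng):
    out = run_generation(Population.empty(), params, rng)
    assert out.size == 0 and out.generation == 1


def test_generation_is_deterministic_and_bounded():
    params = SimParams(x_max=10, y_max=4, K=20)
    rng = np.random.default_rng(9)
    n = 500
    pop = Population(
        x=rng.integers(1, 11, n), y=rng.integers(1, 5, n), T=rng.random(n),
        phenotype=np.zeros(n, np.int8),
    )
    a = pop.copy()
    for _ in range(20):
        a = run_generation(a, params, np.random.default_rng(a.generation))
        assert a.size <= params.n_patches * params.K * params.max_brood
        assert np.all((a.T >= 0) & (a.T <= 1))
    b = pop.copy()
    for _ in range(20):
        b = run_generation(b, params, np.random.default_rng(b.generation))
    np.testing.assert_array_equal(a.T, b.T)
    np.testing.assert_array_equal(a.x, b.x)


def test_without_mutation_no_new_threshold_values():
    params = SimParams(x_max=10, y_max=4, K=20, m=0.0)
    rng = np.random.default_rng(4)
    n = 400
    pop = Population(
        x=rng.integers(1, 11, n), y=rng.integers(1, 5, n),
        T=rng.choice([0.1, 0.4, 0.55, 0.9], n), phenotype=np.zeros(n, np.int8),
    )
    seen = set(np.unique(pop.T))
    for _ in range(15):
        pop = run_generation(pop, params, rng)
        assert set(np.unique(pop.T)) <= seen
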