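"""Growth-engine behaviour: neighbourhoods, division rules, pushing
mechanics, growth modes and determinism."""

import numpy as np
import pytest

from spatialith import (
    ConfigError,
    GrowthEngine,
    LatticeBoundError,
    SimulationConfig,
    grow_tumour,
    neighbor_sites,
    tumour_radius,
)


# ---------------------------------------------------------------- neighbours
def test_moore_neighbourhood_counts_and_members():
    n2 = neighbor_sites((0, 0), 2)
    assert len(n2) == 8 and len(set(n2)) == 8
    n3 = neighbor_sites((0, 0, 0), 3)
    assert len(n3) == 26 and len(set(n3)) == 26
    n = neighbor_sites((5, 7), 2)
    assert (4, 6) in n and (6, 8) in n and (5, 7) not in n


def test_invalid_dimension_rejected():
    with pytest.raises(ConfigError):
        neighbor_sites((0, 0), 4)
    with pytest.raises(ConfigError):
        SimulationConfig(push_rate=0.5, dimension=1)
    with pytest.raises(ConfigError):
        SimulationConfig(push_rate=1.5)
    with pytest.raises(ConfigError):
        SimulationConfig(push_rate=0.5, mutation_rate=-1)


# ---------------------------------------------------------------- divisions
def _enclosed_engine(push_rate, algo="random_direction"):
    """Seeded engine whose centre cell is fully enclosed by a 3x3 block."""
    eng = GrowthEngine(
        SimulationConfig(push_rate=push_rate, mutation_rate=0.0, target_size=64,
                         push_algorithm=algo, seed=1)
    )
    cx = eng.centre[0]
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            if (dx, dy) != (0, 0):
                eng.place_cell((cx + dx, cx + dy))
    return eng


def test_enclosed_cell_never_divides_at_p0():
    eng = _enclosed_engine(0.0)
    for _ in range(50):
        assert eng.attempt_division(0) is None
    assert eng.n_alive == 9


def test_enclosed_cell_always_divides_at_p1():
    eng = _enclosed_engine(1.0)
    before = eng.n_alive
    res = eng.attempt_division(0)
    assert res is not None
    assert eng.n_alive == before + 1
    assert eng.n_pushes == 1


def test_division_with_space_always_succeeds_even_at_p0():
    eng = GrowthEngine(SimulationConfig(push_rate=0.0, mutation_rate=0.0, target_size=64, seed=1))
    res = eng.attempt_division(0)
    assert res is not None
    d1, d2 = res
    assert eng.occupant(eng.centre) == d1
    # displaced daughter sits on a direct neighbour of the seed site
    assert max(abs(a - b) for a, b in zip(eng.coord_of(eng.pos[d2]), eng.centre)) == 1


# ---------------------------------------------------------------- pushing
def test_random_direction_push_shifts_ray_and_conserves_cells():
    eng = GrowthEngine(SimulationConfig(push_rate=1.0, mutation_rate=0.0, target_size=64, seed=1))
    cx = eng.centre[0]
    # occupy two cells on the +x ray; empty at distance 3
    c1 = eng.place_cell((cx + 1, cx))
    c2 = eng.place_cell((cx + 2, cx))
    ids_before = sorted(i for i in eng.lat if i >= 0)
    freed = eng.push_random_direction(eng.centre, (1, 0))
    assert freed == (cx + 1, cx)
    assert eng.occupant((cx + 1, cx)) == -1  # freed for the daughter
    assert eng.occupant((cx + 2, cx)) == c1  # exactly 2 cells shifted one step
    assert eng.occupant((cx + 3, cx)) == c2
    assert sorted(i for i in eng.lat if i >= 0) == ids_before


def test_push_hits_border_raises_sizing_error():
    eng = GrowthEngine(SimulationConfig(push_rate=1.0, mutation_rate=0.0, target_size=4, seed=1))
    cx = eng.centre[0]
    for x in range(cx + 1, eng.side - 1):  # fill ray up to the border ring
        eng.place_cell((x, cx))
    with pytest.raises(LatticeBoundError):
        eng.push_random_direction(eng.centre, (1, 0))


def test_shortest_path_push_moves_single_blocker():
    eng = _enclosed_engine(1.0, algo="shortest_path")
    cx = eng.centre[0]
    blocker = eng.occupant((cx + 1, cx))
    ids_before = sorted(i for i in eng.lat if i >= 0)
    # every empty at Chebyshev 2; nearest Euclidean are the 4 axis sites at d=2
    freed = eng.push_shortest_path(eng.centre)
    assert eng.occupant(freed) == -1
    assert max(abs(a - b) for a, b in zip(freed, eng.centre)) == 1
    assert sorted(i for i in eng.lat if i >= 0) == ids_before


def test_shortest_path_tiebreak_uniform_between_two_equidistant_empties():
    """5x5 occupied block with exactly two empty sites at distance 2 from the
    centre: over many pushes each side is freed-toward about half the time."""
    hits = {-2: 0, 2: 0}
    n_trials = 1000
    for trial in range(n_trials):
        eng = GrowthEngine(
            SimulationConfig(push_rate=1.0, mutation_rate=0.0, target_size=64,
                             push_algorithm="shortest_path", seed=trial)
        )
        cx = eng.centre[0]
        for dx in range(-2, 3):
            for dy in range(-2, 3):
                if (dx, dy) == (0, 0) or (dy == 0 and abs(dx) == 2):
                    continue
                eng.place_cell((cx + dx, cx + dy))
        eng.push_shortest_path(eng.centre)
        filled = [d for d in (-2, 2) if eng.occupant((cx + d, cx)) >= 0]
        assert len(filled) == 1
        hits[filled[0]] += 1
    # binomial(1000, 0.5): +/- 5 sigma band
    assert 420 < hits[2] < 580


# ---------------------------------------------------------------- growth modes
def test_p1_doubles_every_generation():
    eng = GrowthEngine(SimulationConfig(push_rate=1.0, mutation_rate=0.0, target_size=2**8, seed=9))
    for g in range(1, 9):
        eng.step_generation()
        assert eng.n_alive == 2**g


def test_p0_surface_growth_never_pushes(tum_p0_small):
    assert tum_p0_small.n_pushes == 0


def test_growth_speed_monotone_in_push_rate(tumour_cache):
    """Mean generations to reach 2**12 cells is non-increasing in p."""
    mean_gens = []
    for p in (0.0, 0.125, 0.25, 0.5, 1.0):
        gens = []
        for rep in range(20):
            tum = grow_tumour(
                SimulationConfig(push_rate=p, mutation_rate=0.0, target_size=2**12,
                                 seed=7000 + rep)
            )
            gens.append(tum.generation)
        mean_gens.append(np.mean(gens))
    assert all(a >= b for a, b in zip(mean_gens, mean_gens[1:]))
    assert mean_gens[-1] == 12  # exact doubling


def test_identical_seed_gives_bit_identical_tumour():
    cfg = SimulationConfig(push_rate=0.5, mutation_rate=5.0, target_size=2**9, seed=123)
    a = grow_tumour(cfg)
    b = grow_tumour(cfg)
    for attr in ("parent", "birth_gen", "mut_start", "mut_count", "alive", "pos", "lattice"):
        assert np.array_equal(getattr(a, attr), getattr(b, attr))
    assert a.generation == b.generation and a.n_pushes == b.n_pushes


def test_growth_is_per_division_incremental():
    """Cell count rises by exactly one per division; no site ever holds two
    cells (every occupied site maps to a unique alive cell)."""
    cfg = SimulationConfig(push_rate=0.5, mutation_rate=0.0, target_size=2**8, seed=3)
    tum = grow_tumour(cfg)
    occupants = tum.lattice[tum.lattice >= 0]
    assert len(occupants) == len(np.unique(occupants)) == tum.n_cells
    assert np.array_equal(np.sort(occupants), tum.alive_ids())
    # retired cells = alive - 1 divisions, each adding exactly one cell
    assert tum.n_cells_total == 2 * tum.n_cells - 1


# ---------------------------------------------------------------- radius
def test_radius_simple_cases():
    eng = GrowthEngine(SimulationConfig(push_rate=0.0, mutation_rate=0.0, target_size=16, seed=1))
    assert eng.to_tumour().radius() == 0.0
    cx = eng.centre[0]
    eng.place_cell((cx + 1, cx))
    assert eng.to_tumour().radius() == 1.0


def test_surface_tumour_radius_matches_disc_area(tum_p0_small):
    expected = np.sqrt(tum_p0_small.n_cells / np.pi)
    assert abs(tumour_radius(tum_p0_small) - expected) / expected < 0.15
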