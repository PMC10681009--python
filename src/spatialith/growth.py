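"""Agent-based tumour growth on a 2D/3D lattice with a variable push rate.

A tumour grows from a single cell seeded at the centre of a square (cubic)
lattice. Cells occupy lattice sites; each cell's neighbourhood is the Moore
neighbourhood (8 sites in 2D, 26 in 3D). Growth proceeds in synchronous
generations: every cell alive at the start of a generation attempts one
division, in uniformly shuffled order; daughters born within a generation
first act in the next one.

Division rules
--------------
* If the cell has at least one empty direct neighbour, it always divides and
  the new daughter occupies a uniformly chosen empty neighbour.
* If the cell is fully enclosed, it divides with probability ``p`` (the push
  rate) by displacing neighbours to create space. ``p = 0`` yields surface
  growth (only rim cells divide); ``p = 1`` yields exponential growth (every
  cell divides every generation, so N(g) = 2**g).

Two pushing algorithms are implemented:

* ``random_direction`` — pick a uniformly random Moore direction and shift
  the contiguous run of cells along that ray outward by one site, up to the
  first empty site on the ray.
* ``shortest_path`` — locate the empty lattice site nearest to the dividing
  cell (Euclidean distance, ties broken uniformly), and shift the cells along
  a discretized straight-line Moore path toward it by one step.

Both daughters of a division are new genotype nodes: the in-place daughter
keeps the parent's site but receives a fresh cell id, and the parent record
is retired. Cell ids therefore strictly encode birth order. Each daughter
independently draws Poisson(lambda) new mutations (see
:mod:`spatialith.mutations`); mutation ids are sequential, so a cell's
private mutations form a contiguous id range recorded as (start, count).

There is no cell death: the model is pure birth, so the effective mutation
rate inferred downstream equals the per-division rate lambda.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PUSH_RANDOM_DIRECTION",
    "PUSH_SHORTEST_PATH",
    "SimulationConfig",
    "Tumour",
    "GrowthEngine",
    "ConfigError",
    "LatticeBoundError",
    "neighbor_sites",
    "grow_tumour",
    "tumour_radius",
]

PUSH_RANDOM_DIRECTION = "random_direction"
PUSH_SHORTEST_PATH = "shortest_path"

_EMPTY = -1
_BORDER = -2


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class LatticeBoundError(RuntimeError):
    """A push reached the lattice border: the lattice was sized too small."""


def neighbor_sites(coord: Sequence[int], dimension: int) -> list[tuple[int, ...]]:
    """Moore neighbourhood of ``coord``: all sites differing by -1/0/+1 in
    each axis, excluding ``coord`` itself (8 sites in 2D, 26 in 3D).

    The returned order is deterministic (lexicographic in the offsets);
    random choice among neighbours is the caller's RNG's job.
    """
    if dimension not in (2, 3):
        raise ConfigError(f"dimension must be 2 or 3, got {dimension}")
    if len(coord) != dimension:
        raise ConfigError(f"coordinate {coord} does not match dimension {dimension}")
    out = []
    for delta in itertools.product((-1, 0, 1), repeat=dimension):
        if all(d == 0 for d in delta):
            continue
        out.append(tuple(c + d for c, d in zip(coord, delta)))
    return out


def _moore_deltas(dimension: int) -> list[tuple[int, ...]]:
    return [
        d
        for d in itertools.product((-1, 0, 1), repeat=dimension)
        if any(x != 0 for x in d)
    ]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one tumour growth simulation.

    Parameters
    ----------
    push_rate
        Probability ``p`` in [0, 1] that a fully enclosed cell creates
        division space by pushing. 0 = surface growth, 1 = exponential.
    mutation_rate
        Mean number of new (neutral) mutations per daughter cell per
        division; each daughter draws Poisson(mutation_rate) independently.
    dimension
        2 or 3.
    target_size
        Stop at the end of the first generation in which the live cell count
        reaches this value.
    max_generations
        Hard cap on the number of synchronous generations.
    push_algorithm
        ``"random_direction"`` or ``"shortest_path"``.
    seed
        Integer seed for the single RNG driving all stochastic choices.
    detection_limit
        Default mutation-frequency detection threshold used downstream.
    truncation_points
        Default number of lowest-frequency cumulative-curve points dropped
        before regression downstream.
    """

    push_rate: float
    mutation_rate: float = 10.0
    dimension: int = 2
    target_size: int = 2**14
    max_generations: int = 10_000
    push_algorithm: str = PUSH_RANDOM_DIRECTION
    seed: int = 0
    detection_limit: float = 0.01
    truncation_points: int = 3

    def __post_init__(self) -> None:
        if not (0.0 <= self.push_rate <= 1.0):
            raise ConfigError(f"push_rate must be in [0, 1], got {self.push_rate}")
        if self.mutation_rate < 0:
            raise ConfigError("mutation_rate must be non-negative")
        if self.dimension not in (2, 3):
            raise ConfigError(f"dimension must be 2 or 3, got {self.dimension}")
        if self.target_size < 1:
            raise ConfigError("target_size must be >= 1")
        if self.max_generations < 1:
            raise ConfigError("max_generations must be >= 1")
        if self.push_algorithm not in (PUSH_RANDOM_DIRECTION, PUSH_SHORTEST_PATH):
            raise ConfigError(f"unknown push_algorithm {self.push_algorithm!r}")
        if not (0.0 < self.detection_limit < 1.0):
            raise ConfigError("detection_limit must be in (0, 1)")
        if self.truncation_points < 0:
            raise ConfigError("truncation_points must be >= 0")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))


@dataclass
class Tumour:
    """Result of one growth simulation.

    Per-cell arrays are indexed by cell id (0 = the seed). A cell is retired
    when it divides; both products of a division receive fresh ids, so ids
    strictly increase with birth order. ``pos`` holds the current flat
    lattice index for alive cells (stale for retired cells). Each cell's
    private mutations are the contiguous id range
    ``[mut_start[c], mut_start[c] + mut_count[c])``.
    """

    config: SimulationConfig
    side: int
    centre: tuple[int, ...]
    generation: int
    n_pushes: int
    parent: np.ndarray
    birth_gen: np.ndarray
    mut_start: np.ndarray
    mut_count: np.ndarray
    alive: np.ndarray
    pos: np.ndarray
    lattice: np.ndarray  # flat, occupant cell id or _EMPTY / _BORDER

    # -- basic views ---------------------------------------------------
    @property
    def dimension(self) -> int:
        return self.config.dimension

    @property
    def n_cells(self) -> int:
        """Number of alive cells."""
        return int(self.alive.sum())

    @property
    def n_cells_total(self) -> int:
        """Total number of cell records ever created (incl. retired)."""
        return int(self.parent.shape[0])

    @property
    def n_mutations(self) -> int:
        return int(self.mut_start[-1] + self.mut_count[-1]) if self.n_cells_total else 0

    def alive_ids(self) -> np.ndarray:
        return np.flatnonzero(self.alive)

    def coords(self, cell_ids: np.ndarray | None = None, relative: bool = True) -> np.ndarray:
        """Integer lattice coordinates of cells (rows), seed at the origin
        when ``relative`` is true."""
        ids = self.alive_ids() if cell_ids is None else np.asarray(cell_ids)
        flat = self.pos[ids]
        out = self.unravel(flat)
        if relative:
            out = out - np.asarray(self.centre)
        return out

    def unravel(self, flat: np.ndarray) -> np.ndarray:
        return np.stack(
            np.unravel_index(np.asarray(flat), (self.side,) * self.dimension), axis=-1
        )

    def occupancy_grid(self) -> np.ndarray:
        """Boolean occupancy array of shape (side,)*dimension."""
        return (self.lattice >= 0).reshape((self.side,) * self.dimension)

    def lattice_grid(self) -> np.ndarray:
        """Occupant cell id per site (negative = empty/border), nd-shaped."""
        return self.lattice.reshape((self.side,) * self.dimension)

    def radius(self) -> float:
        """Max Euclidean distance from the seed site to any occupied site."""
        if self.n_cells == 0:
            raise ValueError("tumour has no cells")
        rel = self.coords(relative=True)
        return float(np.sqrt((rel.astype(float) ** 2).sum(axis=1).max()))

    # -- tables ---------------------------------------------------------
    def cell_table(self) -> pd.DataFrame:
        """One row per cell record: id, parent, birth generation, alive flag
        and (for alive cells) current lattice coordinates relative to the
        seed. Retired cells have no defined position."""
        n = self.n_cells_total
        axes = "xyz"[: self.dimension]
        df = pd.DataFrame(
            {
                "cell_id": np.arange(n),
                "parent_id": self.parent,
                "birth_generation": self.birth_gen,
                "alive": self.alive.astype(int),
            }
        )
        coords = np.full((n, self.dimension), np.nan)
        ids = self.alive_ids()
        coords[ids] = self.coords(ids)
        for j, ax in enumerate(axes):
            df[ax] = coords[:, j]
        return df

    def mutation_table(self) -> pd.DataFrame:
        """One row per mutation: mutation_id, origin_cell_id, origin_generation."""
        reps = self.mut_count
        origin = np.repeat(np.arange(self.n_cells_total), reps)
        return pd.DataFrame(
            {
                "mutation_id": np.arange(reps.sum(), dtype=np.int64),
                "origin_cell_id": origin,
                "origin_generation": self.birth_gen[origin],
            }
        )


class GrowthEngine:
    """Stateful simulator; :func:`grow_tumour` is the one-shot wrapper.

    All stochastic choices are driven by a single ``numpy`` Generator seeded
    from the config, consumed in a documented order (per generation: shuffle,
    then per-cell placement / push-gate / push-direction uniforms, then the
    batched Poisson mutation draws), so identical configs replay exactly.
    """

    def __init__(self, config: SimulationConfig):
        self.config = config
        dim = config.dimension
        side = 4 * math.ceil(config.target_size ** (1.0 / dim)) + 3
        self.side = side
        self.dim = dim
        self.centre = (side // 2,) * dim
        n_sites = side**dim
        lat = [_EMPTY] * n_sites
        # sentinel border ring so neighbour offsets never wrap across rows
        grid = np.zeros((side,) * dim, dtype=bool)
        for ax in range(dim):
            sl = [slice(None)] * dim
            for edge in (0, side - 1):
                sl[ax] = edge
                grid[tuple(sl)] = True
        for i in np.flatnonzero(grid.ravel()):
            lat[i] = _BORDER
        self.lat = lat
        deltas = _moore_deltas(dim)
        strides = [side ** (dim - 1 - k) for k in range(dim)]
        self.deltas = deltas
        self.strides = strides
        self.offsets = [sum(d * s for d, s in zip(delta, strides)) for delta in deltas]
        self.rng = np.random.default_rng(config.seed)
        # per-cell records (python lists while growing)
        self.parent: list[int] = []
        self.birth_gen: list[int] = []
        self.mut_start: list[int] = []
        self.mut_count: list[int] = []
        self.alive: list[bool] = []
        self.pos: list[int] = []
        self.population: list[int] = []  # alive cell ids
        self.generation = 0
        self.n_pushes = 0
        self._next_mut = 0
        self._ring_cache: dict[int, list[tuple[tuple[int, ...], int]]] = {}
        self.place_cell(self.centre, parent=-1, n_mutations=0)

    # -- lattice helpers -------------------------------------------------
    def flat(self, coord: Sequence[int]) -> int:
        return sum(c * s for c, s in zip(coord, self.strides))

    def coord_of(self, flat: int) -> tuple[int, ...]:
        out = []
        for s in self.strides:
            out.append(flat // s)
            flat %= s
        return tuple(out)

    def occupant(self, coord: Sequence[int]) -> int:
        """Cell id at ``coord`` or -1 if empty (-2 on the border ring)."""
        return self.lat[self.flat(coord)]

    def place_cell(
        self, coord: Sequence[int], parent: int = -1, n_mutations: int = 0, generation: int | None = None
    ) -> int:
        """Create a new cell at an empty site and return its id. Used for the
        seed and for constructing hand-built lattices in tests."""
        i = self.flat(coord)
        if self.lat[i] != _EMPTY:
            raise ValueError(f"site {tuple(coord)} is not empty")
        cid = len(self.parent)
        self.lat[i] = cid
        self.parent.append(parent)
        self.birth_gen.append(self.generation if generation is None else generation)
        self.mut_start.append(self._next_mut)
        self.mut_count.append(n_mutations)
        self._next_mut += n_mutations
        self.alive.append(True)
        self.pos.append(i)
        self.population.append(cid)
        return cid

    @property
    def n_alive(self) -> int:
        return len(self.population)

    # -- pushing ----------------------------------------------------------
    def _push_ray(self, base: int, off: int) -> int:
        """Shift the contiguous run of cells along direction ``off`` outward
        by one site (up to the first empty site on the ray); return the freed
        neighbour site. Occupant multiset is conserved."""
        lat = self.lat
        pos = self.pos
        i = base + off
        chain = []
        v = lat[i]
        while v >= 0:
            chain.append(i)
            i += off
            v = lat[i]
        if v == _BORDER:
            raise LatticeBoundError(
                "push ray hit the lattice border before an empty site; "
                "increase target_size headroom"
            )
        for j in range(len(chain) - 1, -1, -1):
            s = chain[j]
            cid = lat[s]
            lat[s + off] = cid
            pos[cid] = s + off
        freed = base + off
        lat[freed] = _EMPTY
        self.n_pushes += 1
        return freed

    def push_random_direction(self, origin: Sequence[int], direction: Sequence[int]) -> tuple[int, ...]:
        """Public wrapper for tests: push from ``origin`` along a Moore
        ``direction``; returns the freed neighbour coordinate."""
        off = sum(d * s for d, s in zip(direction, self.strides))
        freed = self._push_ray(self.flat(origin), off)
        return self.coord_of(freed)

    def _ring(self, r: int) -> list[tuple[tuple[int, ...], int]]:
        """Chebyshev ring offsets at radius r with squared Euclidean norms."""
        cached = self._ring_cache.get(r)
        if cached is None:
            cached = [
                (d, sum(x * x for x in d))
                for d in itertools.product(range(-r, r + 1), repeat=self.dim)
                if max(abs(x) for x in d) == r
            ]
            self._ring_cache[r] = cached
        return cached

    def _push_shortest(self, base: int) -> int:
        """Push toward the empty lattice site nearest to ``base`` (Euclidean,
        ties uniform) along a discretized straight-line Moore path; return
        the freed neighbour site."""
        lat = self.lat
        origin = self.coord_of(base)
        side = self.side
        best: list[tuple[int, ...]] = []
        best_d2 = None
        r = 1
        while True:
            if best_d2 is not None and r * r > best_d2:
                break
            if r >= side:
                raise LatticeBoundError("no empty site found within the lattice")
            for delta, d2 in self._ring(r):
                if best_d2 is not None and d2 > best_d2:
                    continue
                c = tuple(o + d for o, d in zip(origin, delta))
                if any(x < 0 or x >= side for x in c):
                    continue
                if lat[self.flat(c)] == _EMPTY:
                    if best_d2 is None or d2 < best_d2:
                        best_d2 = d2
                        best = [c]
                    elif d2 == best_d2:
                        best.append(c)
            r += 1
        tgt = best[int(self.rng.random() * len(best))] if len(best) > 1 else best[0]
        # greedy sign-stepped Moore path (discretized segment origin -> tgt)
        path = [base]
        cur = origin
        while cur != tgt:
            cur = tuple(c + (t > c) - (t < c) for c, t in zip(cur, tgt))
            path.append(self.flat(cur))
        # first empty site along the path (the target, or an equidistant one)
        e = 1
        while lat[path[e]] != _EMPTY:
            e += 1
        pos = self.pos
        for j in range(e, 1, -1):
            cid = lat[path[j - 1]]
            lat[path[j]] = cid
            pos[cid] = path[j]
        freed = path[1]
        lat[freed] = _EMPTY
        self.n_pushes += 1
        return freed

    def push_shortest_path(self, origin: Sequence[int]) -> tuple[int, ...]:
        """Public wrapper for tests; returns the freed neighbour coordinate."""
        return self.coord_of(self._push_shortest(self.flat(origin)))

    # -- division ---------------------------------------------------------
    def _divide(self, cell: int, base: int, site: int, k1: int, k2: int, gen: int) -> tuple[int, int]:
        self.alive[cell] = False
        d1 = len(self.parent)
        d2 = d1 + 1
        # in-place daughter at the parent's site
        self.parent.append(cell)
        self.birth_gen.append(gen)
        self.mut_start.append(self._next_mut)
        self.mut_count.append(k1)
        self._next_mut += k1
        self.alive.append(True)
        self.pos.append(base)
        self.lat[base] = d1
        # displaced daughter at the new site
        self.parent.append(cell)
        self.birth_gen.append(gen)
        self.mut_start.append(self._next_mut)
        self.mut_count.append(k2)
        self._next_mut += k2
        self.alive.append(True)
        self.pos.append(site)
        self.lat[site] = d2
        return d1, d2

    def attempt_division(self, cell_id: int) -> tuple[int, int] | None:
        """Single-cell division attempt using fresh RNG draws (the generation
        loop uses the same logic with batched draws). Returns the daughter
        ids, or None if the cell was enclosed and the push gate failed."""
        if not self.alive[cell_id]:
            raise ValueError(f"cell {cell_id} is not alive")
        rng = self.rng
        u_place = float(rng.random())
        u_push = float(rng.random())
        u_dir = float(rng.random())
        if self.config.mutation_rate > 0:
            k1, k2 = (int(k) for k in rng.poisson(self.config.mutation_rate, 2))
        else:
            k1 = k2 = 0
        res = self._attempt(cell_id, u_place, u_push, u_dir, k1, k2, self.generation + 1)
        if res is not None:
            self.population = [c for c in self.population if c != cell_id] + list(res)
        return res

    def _attempt(
        self, cell: int, u_place: float, u_push: float, u_dir: float, k1: int, k2: int, gen: int
    ) -> tuple[int, int] | None:
        lat = self.lat
        base = self.pos[cell]
        empties = [base + off for off in self.offsets if lat[base + off] == _EMPTY]
        if empties:
            site = empties[int(u_place * len(empties))]
        elif u_push < self.config.push_rate:
            if self.config.push_algorithm == PUSH_RANDOM_DIRECTION:
                site = self._push_ray(base, self.offsets[int(u_dir * len(self.offsets))])
            else:
                site = self._push_shortest(base)
        else:
            return None
        return self._divide(cell, base, site, k1, k2, gen)

    # -- generation loop ----------------------------------------------------
    def step_generation(self) -> None:
        """Run one synchronous generation: every cell alive at its start
        attempts one division, in uniformly shuffled order."""
        gen = self.generation + 1
        rng = self.rng
        pop = self.population
        n = len(pop)
        order = rng.permutation(np.asarray(pop, dtype=np.int64)).tolist()
        u_place = rng.random(n)
        u_push = rng.random(n)
        u_dir = rng.random(n)
        lam = self.config.mutation_rate
        kdraw = rng.poisson(lam, 2 * n) if lam > 0 else np.zeros(2 * n, dtype=np.int64)
        kdraw = kdraw.tolist()
        u_place_l = u_place.tolist()
        u_push_l = u_push.tolist()
        u_dir_l = u_dir.tolist()
        new_pop = []
        ki = 0
        attempt = self._attempt
        for i, cell in enumerate(order):
            res = attempt(cell, u_place_l[i], u_push_l[i], u_dir_l[i], kdraw[ki], kdraw[ki + 1], gen)
            ki += 2
            if res is None:
                new_pop.append(cell)
            else:
                new_pop.append(res[0])
                new_pop.append(res[1])
        self.population = new_pop
        self.generation = gen

    def run(self, progress: Callable[[int, int], None] | None = None) -> Tumour:
        cfg = self.config
        while self.n_alive < cfg.target_size and self.generation < cfg.max_generations:
            self.step_generation()
            if progress is not None:
                progress(self.generation, self.n_alive)
        return self.to_tumour()

    def to_tumour(self) -> Tumour:
        return Tumour(
            config=self.config,
            side=self.side,
            centre=self.centre,
            generation=self.generation,
            n_pushes=self.n_pushes,
            parent=np.asarray(self.parent, dtype=np.int64),
            birth_gen=np.asarray(self.birth_gen, dtype=np.int32),
            mut_start=np.asarray(self.mut_start, dtype=np.int64),
            mut_count=np.asarray(self.mut_count, dtype=np.int64),
            alive=np.asarray(self.alive, dtype=bool),
            pos=np.asarray(self.pos, dtype=np.int64),
            lattice=np.asarray(self.lat, dtype=np.int64),
        )


def grow_tumour(
    config: SimulationConfig, progress: Callable[[int, int], None] | None = None
) -> Tumour:
    """Grow one tumour from a single seeded cell under ``config``.

    Stops at the end of the first generation in which the live cell count
    reaches ``config.target_size``, or after ``config.max_generations``
    (reaching the cap is not an error: the tumour grown so far is returned,
    which is how fixed-duration surface-growth runs are expressed).
    """
    return GrowthEngine(config).run(progress=progress)


def tumour_radius(tumour: Tumour) -> float:
    """Max Euclidean distance from the seed site to any occupied site."""
    return tumour.radius()
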