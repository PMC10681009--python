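"""Neutral mutation accumulation and frequency spectra.

Every daughter cell at every division receives k ~ Poisson(lambda) new
mutations (P(k) = lambda**k * exp(-lambda) / k!). Mutation ids are assigned
sequentially at birth, so a cell's private mutations are a contiguous id
range and a mutation's carriers are exactly the alive descendants of its
origin cell. Genotypes are never stored explicitly: a cell's mutation set is
the union of private sets along its ancestry chain, and carrier counts are
obtained by accumulating subtree sizes over the (forest-ordered) cell table.

Frequencies are reported as *cell fractions* f_c = carriers / universe size,
the model's native convention; the diploid variant-allele frequency of a
heterozygous mutation is f_c / 2 (see :mod:`spatialith.vaf`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "CELL_FRACTION",
    "DIPLOID_VAF",
    "FrequencySpectrum",
    "draw_new_mutations",
    "resolve_mutation_set",
    "subtree_carrier_counts",
    "mutation_frequencies",
    "track_early_mutations",
]

CELL_FRACTION = "cell_fraction"
DIPLOID_VAF = "diploid_vaf"


@dataclass(frozen=True)
class FrequencySpectrum:
    """Mutation frequencies over a stated universe of cells.

    ``fractions[i]`` is the frequency of ``mutation_ids[i]`` in the universe,
    in the stated convention (cell fraction by default). Only mutations
    carried by at least one universe cell appear.
    """

    mutation_ids: np.ndarray
    fractions: np.ndarray
    universe_size: int
    convention: str = CELL_FRACTION

    def __post_init__(self) -> None:
        if self.convention not in (CELL_FRACTION, DIPLOID_VAF):
            raise ValueError(f"unknown convention {self.convention!r}")

    def __len__(self) -> int:
        return int(self.mutation_ids.shape[0])

    def to_diploid_vaf(self) -> "FrequencySpectrum":
        """Convert cell fractions to heterozygous-diploid VAF (f_c / 2)."""
        if self.convention == DIPLOID_VAF:
            return self
        return replace(self, fractions=self.fractions / 2.0, convention=DIPLOID_VAF)

    def table(self) -> pd.DataFrame:
        carriers = np.rint(self.fractions * self.universe_size).astype(np.int64)
        if self.convention == DIPLOID_VAF:
            carriers = np.rint(self.fractions * 2 * self.universe_size).astype(np.int64)
        return pd.DataFrame(
            {
                "mutation_id": self.mutation_ids,
                "carriers": carriers,
                "universe_size": self.universe_size,
                self.convention: self.fractions,
            }
        )


def draw_new_mutations(mutation_rate: float, rng: np.random.Generator, start_id: int = 0) -> np.ndarray:
    """Draw k ~ Poisson(mutation_rate) fresh mutation ids for one daughter.

    Returns ``arange(start_id, start_id + k)``; the growth engine applies the
    same draw in batched form and records only ``(start_id, k)`` per cell.
    """
    if mutation_rate < 0:
        raise ValueError("mutation_rate must be non-negative")
    k = int(rng.poisson(mutation_rate)) if mutation_rate > 0 else 0
    return np.arange(start_id, start_id + k, dtype=np.int64)


def resolve_mutation_set(tumour, cell_id: int) -> np.ndarray:
    """All mutation ids carried by ``cell_id``: the union of private ranges
    along the parent chain up to the seed (which carries none)."""
    n = tumour.parent.shape[0]
    if not (0 <= cell_id < n):
        raise KeyError(f"unknown cell id {cell_id}")
    parts = []
    c = int(cell_id)
    while c >= 0:
        k = int(tumour.mut_count[c])
        if k:
            s = int(tumour.mut_start[c])
            parts.append(np.arange(s, s + k, dtype=np.int64))
        c = int(tumour.parent[c])
    if not parts:
        return np.empty(0, dtype=np.int64)
    return np.sort(np.concatenate(parts))


def subtree_carrier_counts(tumour, universe: np.ndarray) -> np.ndarray:
    """For every cell record c, the number of universe cells in c's subtree
    (c included). This is the carrier count, within the universe, of every
    mutation private to c.

    Works level-by-level over birth generations (a parent is always born
    strictly before its daughters), fully vectorised per level.
    """
    parent = tumour.parent
    birth = tumour.birth_gen
    cnt = np.zeros(parent.shape[0], dtype=np.int64)
    universe = np.asarray(universe)
    if universe.size == 0:
        raise ValueError("empty cell universe")
    cnt[universe] = 1
    for g in np.unique(birth)[::-1]:
        if g == 0:
            break
        ids = np.flatnonzero(birth == g)
        ids = ids[cnt[ids] > 0]
        if ids.size:
            np.add.at(cnt, parent[ids], cnt[ids])
    return cnt


def _expand_ranges(starts: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Concatenate arange(start, start+count) over rows, vectorised."""
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    reps = np.repeat(starts, counts)
    within = np.arange(total, dtype=np.int64) - np.repeat(
        np.concatenate(([0], np.cumsum(counts)[:-1])), counts
    )
    return reps + within


def mutation_frequencies(tumour, universe: np.ndarray | None = None) -> FrequencySpectrum:
    """Cell-fraction spectrum of all mutations carried by >= 1 universe cell.

    ``universe`` defaults to all alive cells (whole-tumour spectrum); pass a
    sample's member cell ids for a within-sample spectrum.
    """
    if universe is None:
        universe = tumour.alive_ids()
    universe = np.asarray(universe, dtype=np.int64)
    if universe.size == 0:
        raise ValueError("empty cell universe")
    cnt = subtree_carrier_counts(tumour, universe)
    sel = np.flatnonzero((tumour.mut_count > 0) & (cnt > 0))
    ids = _expand_ranges(tumour.mut_start[sel], tumour.mut_count[sel])
    fr = np.repeat(cnt[sel], tumour.mut_count[sel]) / float(universe.size)
    return FrequencySpectrum(
        mutation_ids=ids,
        fractions=fr,
        universe_size=int(universe.size),
        convention=CELL_FRACTION,
    )


def track_early_mutations(tumour, up_to_generation: int) -> pd.DataFrame:
    """Final whole-tumour cell fractions of all mutations that originated in
    generations 1..up_to_generation.

    Columns: mutation_id, origin_generation, cell_fraction. With no cell
    death every mutation keeps at least one carrier, so all early mutations
    appear. Aggregate over replicates for mean/variance per generation.
    """
    alive = tumour.alive_ids()
    cnt = subtree_carrier_counts(tumour, alive)
    sel = np.flatnonzero(
        (tumour.mut_count > 0)
        & (tumour.birth_gen >= 1)
        & (tumour.birth_gen <= up_to_generation)
    )
    ids = _expand_ranges(tumour.mut_start[sel], tumour.mut_count[sel])
    gens = np.repeat(tumour.birth_gen[sel], tumour.mut_count[sel])
    fr = np.repeat(cnt[sel], tumour.mut_count[sel]) / float(alive.size)
    return pd.DataFrame(
        {"mutation_id": ids, "origin_generation": gens, "cell_fraction": fr}
    )
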