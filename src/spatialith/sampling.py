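"""Spatial sampling of simulated tumours.

Samples are axis-aligned squares (cubes in 3D) of side ``s = round(S**(1/d))``
for a requested size of ``S`` cells, centred on uniformly drawn occupied
lattice sites. A candidate is accepted only when its box is fully occupied,
so every emitted sample contains exactly ``s**d`` cells; partially empty
boxes near the tumour rim are rejected and redrawn. Samples may overlap one
another at draw time — pair-level analyses filter to non-overlapping pairs.

Centre/margin classification: a sample is "centre" when its centre lies
within two-thirds of the tumour radius R from the seed site (inclusive),
otherwise "margin" (the outer one-third ring).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .growth import Tumour

__all__ = [
    "Sample",
    "SamplingError",
    "random_square_samples",
    "centre_margin_partition",
    "sample_distance",
    "non_overlapping",
    "sample_table",
    "membership_table",
]

REGION_RANDOM = "random"
REGION_CENTRE = "centre"
REGION_MARGIN = "margin"


class SamplingError(RuntimeError):
    """Could not draw the requested samples within the attempt cap."""


@dataclass
class Sample:
    """One square/cubic cell sample.

    ``centre`` is the lattice coordinate the box is anchored on (the box
    spans ``[c - s//2, c - s//2 + s)`` per axis); ``diameter`` equals the
    side, which is also the shortest centre distance of two non-overlapping
    equal-size samples.
    """

    sample_id: int
    centre: tuple[int, ...]
    side: int
    cell_ids: np.ndarray
    region: str = REGION_RANDOM

    @property
    def size(self) -> int:
        return int(self.cell_ids.shape[0])

    @property
    def diameter(self) -> int:
        return self.side

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.asarray(self.centre) - self.side // 2
        return lo, lo + self.side


def _integral_image(grid: np.ndarray) -> np.ndarray:
    ii = grid.astype(np.int64)
    for ax in range(grid.ndim):
        ii = ii.cumsum(axis=ax)
    ii = np.pad(ii, [(1, 0)] * grid.ndim)
    return ii


def _box_sum(ii: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> int:
    """Occupied-site count in the half-open box [lo, hi) via the padded
    integral image (inclusion–exclusion over the 2**d corners)."""
    d = lo.shape[0]
    total = 0
    for mask in range(1 << d):
        idx = tuple(hi[k] if not (mask >> k) & 1 else lo[k] for k in range(d))
        total += (-1) ** bin(mask).count("1") * int(ii[idx])
    return total


def random_square_samples(
    tumour: Tumour,
    sample_size: int,
    n_samples: int,
    rng: np.random.Generator,
    region: str | None = None,
    max_attempts: int = 10**6,
) -> list[Sample]:
    """Draw ``n_samples`` fully occupied square (cubic) samples of
    ``sample_size`` cells, centres uniform among occupied sites.

    ``region`` restricts candidate centres to the centre (within (2/3)R of
    the seed, inclusive) or margin region; samples are then labelled
    accordingly. Raises :class:`SamplingError` with the observed acceptance
    rate if the attempt cap is hit.
    """
    dim = tumour.dimension
    s = round(sample_size ** (1.0 / dim))
    if s < 1:
        raise ValueError("sample_size too small")
    if sample_size > tumour.n_cells:
        raise ValueError("sample_size exceeds tumour size")
    grid = tumour.occupancy_grid()
    ii = _integral_image(grid)
    lat = tumour.lattice_grid()
    occupied = np.argwhere(grid)
    if region in (REGION_CENTRE, REGION_MARGIN):
        rel = occupied - np.asarray(tumour.centre)
        dist = np.sqrt((rel.astype(float) ** 2).sum(axis=1))
        cut = (2.0 / 3.0) * tumour.radius()
        keep = dist <= cut if region == REGION_CENTRE else dist > cut
        occupied = occupied[keep]
        if occupied.shape[0] == 0:
            raise SamplingError(f"no occupied sites in region {region!r}")
    elif region is not None and region != REGION_RANDOM:
        raise ValueError(f"unknown region {region!r}")
    half = s // 2
    samples: list[Sample] = []
    attempts = 0
    volume = s**dim
    side = tumour.side
    while len(samples) < n_samples:
        if attempts >= max_attempts:
            raise SamplingError(
                f"attempt cap {max_attempts} reached after accepting "
                f"{len(samples)}/{n_samples} samples "
                f"(acceptance rate {len(samples) / max(attempts, 1):.2e})"
            )
        batch = min(4096, max_attempts - attempts)
        idx = rng.integers(0, occupied.shape[0], size=batch)
        for j in idx:
            attempts += 1
            c = occupied[j]
            lo = c - half
            hi = lo + s
            if (lo < 0).any() or (hi > side).any():
                continue
            if _box_sum(ii, lo, hi) == volume:
                members = lat[tuple(slice(a, b) for a, b in zip(lo, hi))].ravel()
                samples.append(
                    Sample(
                        sample_id=len(samples),
                        centre=tuple(int(x) for x in c),
                        side=s,
                        cell_ids=np.sort(members),
                        region=region or REGION_RANDOM,
                    )
                )
                if len(samples) == n_samples:
                    break
    return samples


def centre_margin_partition(tumour: Tumour, sample: Sample) -> str:
    """Label a sample 'centre' if its centre lies within (2/3)R of the seed
    (boundary inclusive), else 'margin'."""
    rel = np.asarray(sample.centre, dtype=float) - np.asarray(tumour.centre)
    d = float(np.sqrt((rel**2).sum()))
    return REGION_CENTRE if d <= (2.0 / 3.0) * tumour.radius() else REGION_MARGIN


def sample_distance(a: Sample, b: Sample) -> float:
    """Euclidean distance between sample centres, in lattice units."""
    da = np.asarray(a.centre, dtype=float) - np.asarray(b.centre, dtype=float)
    return float(np.sqrt((da**2).sum()))


def non_overlapping(a: Sample, b: Sample) -> bool:
    """True iff the two axis-aligned boxes share no lattice site."""
    lo_a, hi_a = a.bounds()
    lo_b, hi_b = b.bounds()
    return bool(((hi_a <= lo_b) | (hi_b <= lo_a)).any())


def sample_table(samples: list[Sample]) -> pd.DataFrame:
    """Wide-format sample table (cell ids semicolon-joined)."""
    dim = len(samples[0].centre) if samples else 2
    axes = "xyz"[:dim]
    rows = []
    for s in samples:
        row = {"sample_id": s.sample_id, "region": s.region, "side": s.side}
        for j, ax in enumerate(axes):
            row[f"centre_{ax}"] = s.centre[j]
        row["cell_ids"] = ";".join(str(int(c)) for c in s.cell_ids)
        rows.append(row)
    return pd.DataFrame(rows)


def membership_table(samples: list[Sample]) -> pd.DataFrame:
    """Long-format membership table: one (sample_id, cell_id) row per member."""
    sid = np.concatenate([np.full(s.size, s.sample_id) for s in samples])
    cid = np.concatenate([s.cell_ids for s in samples])
    return pd.DataFrame({"sample_id": sid, "cell_id": cid})
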