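"""Synthetic multi-region biopsy tables.

Stand-in generator emulating published multi-region sequencing studies of
single solid tumours (~23 whole-exome biopsies is typical): binary mutation
presence across a couple dozen samples whose sharing decays with physical
distance. All outputs are synthetic; the generator exists so the biopsy-mode
analyses (distance normalisation, clonality filters, Jaccard–distance
correlation) are exercised end-to-end without any patient data.

Model: samples are placed uniformly in a disc of radius 1. Each sub-clonal
mutation j has an origin point uniform in the disc and a base prevalence
q_j ~ U(0.2, 0.8); it is present in sample i with probability
q_j * exp(-spatial_decay * d_ij), where d_ij is the sample–origin distance.
``spatial_decay = 0`` removes all spatial structure (presence is i.i.d.
Bernoulli(q_j), so Jaccard is independent of distance); large decay makes
sharing strictly local, so Jaccard falls with distance. A configurable
fraction of mutations is clonal (present in every sample).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .ith import BiopsyTable

__all__ = ["generate_biopsy_table", "write_biopsy_fixture"]


def _uniform_disc(n: int, rng: np.random.Generator) -> np.ndarray:
    r = np.sqrt(rng.random(n))
    theta = rng.random(n) * 2 * np.pi
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def generate_biopsy_table(
    n_samples: int = 23,
    n_mutations: int = 400,
    spatial_decay: float = 5.0,
    clonal_fraction: float = 0.1,
    rng: np.random.Generator | int | None = None,
) -> BiopsyTable:
    """Generate a synthetic sample x mutation presence table with coordinates.

    Defaults emulate a ~23-biopsy whole-exome multi-region study with
    spatially decaying mutation sharing and a small clonal trunk.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    if not (0.0 <= clonal_fraction <= 1.0):
        raise ValueError("clonal_fraction must be in [0, 1]")
    if spatial_decay < 0:
        raise ValueError("spatial_decay must be non-negative")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    xy = _uniform_disc(n_samples, rng)
    n_clonal = int(round(clonal_fraction * n_mutations))
    n_sub = n_mutations - n_clonal
    origins = _uniform_disc(n_sub, rng)
    q = rng.uniform(0.2, 0.8, size=n_sub)
    d = np.sqrt(((xy[:, None, :] - origins[None, :, :]) ** 2).sum(axis=2))
    prob = q[None, :] * np.exp(-spatial_decay * d)
    presence_sub = (rng.random((n_samples, n_sub)) < prob).astype(np.int8)
    presence = np.concatenate(
        [np.ones((n_samples, n_clonal), dtype=np.int8), presence_sub], axis=1
    )
    sample_ids = [f"S{i + 1:02d}" for i in range(n_samples)]
    presence_df = pd.DataFrame(
        presence, index=pd.Index(sample_ids, name="sample_id"),
        columns=pd.RangeIndex(n_mutations, name="mutation_id"),
    )
    coords = pd.DataFrame(
        {"x": xy[:, 0], "y": xy[:, 1]}, index=pd.Index(sample_ids, name="sample_id")
    )
    return BiopsyTable(presence_df, coords=coords)


def write_biopsy_fixture(
    outdir: str | Path,
    n_samples: int = 23,
    n_mutations: int = 400,
    spatial_decay: float = 5.0,
    clonal_fraction: float = 0.1,
    seed: int = 0,
) -> tuple[Path, Path]:
    """Write a synthetic biopsy fixture as two TSVs: a long-format presence
    table (sample_id, mutation_id) and a coordinates table (sample_id, x, y).
    Returns the two paths."""
    table = generate_biopsy_table(
        n_samples=n_samples,
        n_mutations=n_mutations,
        spatial_decay=spatial_decay,
        clonal_fraction=clonal_fraction,
        rng=seed,
    )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    long = table.presence.stack()
    long = long[long > 0].reset_index()[["sample_id", "mutation_id"]]
    presence_path = outdir / "biopsy_presence.tsv"
    coords_path = outdir / "biopsy_coords.tsv"
    long.to_csv(presence_path, sep="\t", index=False)
    table.coords.reset_index().to_csv(coords_path, sep="\t", index=False)
    return presence_path, coords_path
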