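"""Seeded experiment sweeps: grow -> sample -> Jaccard -> VAF inference.

An :class:`ExperimentPlan` is a grid over push rates, sampling sizes and
sampling methods with a replicate count and a base seed; run seeds are
``base_seed + run_index``, so every run is independently reproducible and a
rerun of the same plan reproduces the output tables byte for byte. Each run
directory holds the standard TSVs plus a JSON manifest (config echo, seed,
package version) written last — a valid manifest marks the run complete, so
interrupted sweeps resume by skipping completed runs; an unreadable manifest
aborts the resume rather than silently overwriting.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .growth import PUSH_RANDOM_DIRECTION, SimulationConfig, grow_tumour
from .ith import jaccard_distance_table
from .io import (
    read_manifest,
    write_cell_table,
    write_jaccard_records,
    write_manifest,
    write_mutation_table,
    write_sample_tables,
)
from .mutations import mutation_frequencies
from .sampling import random_square_samples
from .vaf import CumulativeVAFModel

__all__ = ["ExperimentPlan", "run_experiment"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExperimentPlan:
    """Grid of simulation/analysis runs.

    Defaults mirror the standard study conditions: mutation rate 10 per
    daughter per division, 2D lattice, final size 2**14 cells, 500 random
    sample locations, detection limit 0.01, 3-point truncation.
    """

    push_rates: tuple[float, ...] = (0.0, 1.0)
    sample_sizes: tuple[int, ...] = (100,)
    sampling_methods: tuple[str, ...] = ("random",)
    replicates: int = 1
    mutation_rate: float = 10.0
    dimension: int = 2
    target_size: int = 2**14
    max_generations: int = 10_000
    push_algorithm: str = PUSH_RANDOM_DIRECTION
    n_sample_locations: int = 500
    detection_limit: float = 0.01
    truncation_points: int = 3
    base_seed: int = 0

    def runs(self):
        """Yield (run_index, push_rate, sample_size, method, replicate, seed)."""
        grid = itertools.product(
            self.push_rates, self.sample_sizes, self.sampling_methods, range(self.replicates)
        )
        for idx, (p, size, method, rep) in enumerate(grid):
            yield idx, p, size, method, rep, self.base_seed + idx

    @property
    def n_runs(self) -> int:
        return (
            len(self.push_rates)
            * len(self.sample_sizes)
            * len(self.sampling_methods)
            * self.replicates
        )


def _run_one(plan: ExperimentPlan, outdir: Path, idx: int, p: float, size: int,
             method: str, rep: int, seed: int) -> pd.DataFrame:
    cfg = SimulationConfig(
        push_rate=p,
        mutation_rate=plan.mutation_rate,
        dimension=plan.dimension,
        target_size=plan.target_size,
        max_generations=plan.max_generations,
        push_algorithm=plan.push_algorithm,
        seed=seed,
        detection_limit=plan.detection_limit,
        truncation_points=plan.truncation_points,
    )
    growth_log: list[tuple[int, int]] = []

    def progress(gen: int, n: int) -> None:
        growth_log.append((gen, n))
        logger.info("run %d gen %d: %d cells", idx, gen, n)

    tumour = grow_tumour(cfg, progress=progress)
    logger.info("run %d grown: %d cells in %d generations", idx, tumour.n_cells, tumour.generation)
    rng = np.random.default_rng(seed + 1_000_003)
    regions = ["centre", "margin"] if method == "centre_margin" else [None]
    samples = []
    for region in regions:
        n_loc = plan.n_sample_locations // len(regions) if len(regions) > 1 else plan.n_sample_locations
        samples.extend(random_square_samples(tumour, size, n_loc, rng, region=region))
    for i, s in enumerate(samples):
        s.sample_id = i
    logger.info("run %d sampled: %d samples of %d cells", idx, len(samples), size)
    records = jaccard_distance_table(samples, tumour=tumour, pairing="ordered")
    logger.info("run %d jaccard: %d pairwise records", idx, len(records))

    rows = []
    whole = mutation_frequencies(tumour)
    fit = CumulativeVAFModel.from_spectrum(
        whole, detection_limit=plan.detection_limit, truncation_points=plan.truncation_points
    ).fit()
    rows.append(("whole_tumour", fit))
    for s in samples[: min(len(samples), 50)]:  # per-sample fits on a capped subset
        spec = mutation_frequencies(tumour, s.cell_ids)
        try:
            sfit = CumulativeVAFModel.from_spectrum(
                spec, detection_limit=plan.detection_limit, truncation_points=plan.truncation_points
            ).fit()
        except ValueError:
            continue
        rows.append((f"sample_{s.sample_id}", sfit))
    inference = pd.DataFrame(
        [
            {
                "unit": name,
                "replicate": rep,
                "push_rate": p,
                "sample_size": size,
                "slope": f.mutation_rate,
                "intercept": f.intercept,
                "ks_distance": f.ks_dist,
                "n_points": f.n_points,
            }
            for name, f in rows
        ]
    )

    write_cell_table(tumour, outdir / "cells.tsv")
    write_mutation_table(tumour, outdir / "mutations.tsv")
    write_sample_tables(samples, outdir / "samples.tsv", outdir / "membership.tsv")
    write_jaccard_records(records, outdir / "jaccard.tsv")
    inference.to_csv(outdir / "inference.tsv", sep="\t", index=False)
    pd.DataFrame(growth_log, columns=["generation", "n_cells"]).to_csv(
        outdir / "growth_log.tsv", sep="\t", index=False
    )
    manifest = {
        "config": dataclasses.asdict(cfg),
        "seed": seed,
        "run_index": idx,
        "sampling_method": method,
        "sample_size": size,
        "replicate": rep,
        "version": __version__,
        "n_cells": tumour.n_cells,
        "generations": tumour.generation,
    }
    write_manifest(manifest, outdir / "manifest.json")
    return inference


def run_experiment(plan: ExperimentPlan, outdir: str | Path) -> Path:
    """Execute every run of the plan under ``outdir`` (one subdirectory per
    run) and write a combined ``inference_summary.tsv``. Completed runs
    (valid manifest present) are skipped, making interrupted sweeps
    resumable."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summaries = []
    for idx, p, size, method, rep, seed in plan.runs():
        run_dir = outdir / f"run_{idx:04d}"
        manifest_path = run_dir / "manifest.json"
        if manifest_path.exists():
            try:
                read_manifest(manifest_path)
            except (json.JSONDecodeError, OSError) as exc:
                raise RuntimeError(
                    f"corrupted manifest {manifest_path}; refusing to resume"
                ) from exc
            logger.info("run %d already complete, skipping", idx)
            summaries.append(pd.read_csv(run_dir / "inference.tsv", sep="\t"))
            continue
        run_dir.mkdir(parents=True, exist_ok=True)
        summaries.append(_run_one(plan, run_dir, idx, p, size, method, rep, seed))
    pd.concat(summaries, ignore_index=True).to_csv(
        outdir / "inference_summary.tsv", sep="\t", index=False
    )
    write_manifest(
        {"plan": dataclasses.asdict(plan), "version": __version__, "n_runs": plan.n_runs},
        outdir / "plan_manifest.json",
    )
    return outdir
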