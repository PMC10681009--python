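"""Plain-TSV readers/writers and YAML config round-tripping.

Every output is a flat TSV with a one-line header (desk-inspectable, diffable,
deterministic bytes for a given simulation), plus a JSON manifest per run.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .growth import SimulationConfig, Tumour
from .mutations import FrequencySpectrum
from .sampling import Sample, membership_table, sample_table
from .vaf import CumulativeCurve

__all__ = [
    "save_config",
    "load_config",
    "write_cell_table",
    "write_mutation_table",
    "write_frequency_table",
    "write_sample_tables",
    "read_membership_table",
    "write_jaccard_records",
    "read_jaccard_records",
    "write_curve",
    "write_inference_summary",
    "write_manifest",
    "read_manifest",
]


def save_config(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)


def load_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return SimulationConfig(**raw)


def _write(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def write_cell_table(tumour: Tumour, path: str | Path) -> Path:
    return _write(tumour.cell_table(), path)


def write_mutation_table(tumour: Tumour, path: str | Path) -> Path:
    return _write(tumour.mutation_table(), path)


def write_frequency_table(spectrum: FrequencySpectrum, path: str | Path) -> Path:
    return _write(spectrum.table(), path)


def write_sample_tables(samples: list[Sample], path: str | Path, membership_path: str | Path | None = None) -> Path:
    p = _write(sample_table(samples), path)
    if membership_path is not None:
        _write(membership_table(samples), membership_path)
    return p


def read_membership_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_jaccard_records(records: pd.DataFrame, path: str | Path) -> Path:
    return _write(records, path)


def read_jaccard_records(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_curve(curve: CumulativeCurve, path: str | Path, fitted: np.ndarray | None = None) -> Path:
    df = curve.table()
    if fitted is not None:
        df["fitted_value"] = fitted
    return _write(df, path)


def write_inference_summary(rows: pd.DataFrame, path: str | Path) -> Path:
    return _write(rows, path)


def write_manifest(manifest: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return path


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
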