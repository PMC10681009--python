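"""Jaccard index, clonality filters, pairwise tables and trend summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spatialith import (
    BiopsyTable,
    SimulationConfig,
    distance_trend_summary,
    grow_tumour,
    jaccard,
    jaccard_distance_table,
    random_square_samples,
    subclonal_filter,
)
from spatialith.growth import Tumour


# ---------------------------------------------------------------- jaccard
def test_jaccard_basic_values():
    assert jaccard({1, 2, 3}, {2, 3, 4}) == 0.5
    assert jaccard({5, 6}, {5, 6}) == 1.0
    assert jaccard({1}, {2}) == 0.0
    assert jaccard(set(), set()) == 0.0  # empty-vs-empty convention
    assert jaccard(set(), {1}) == 0.0


@settings(derandomize=True, max_examples=50)
@given(
    a=st.sets(st.integers(0, 50), max_size=20),
    b=st.sets(st.integers(0, 50), max_size=20),
)
def test_jaccard_bounds_symmetry_and_relabelling(a, b):
    j = jaccard(a, b)
    assert 0.0 <= j <= 1.0
    assert j == jaccard(b, a)
    # invariant to a consistent relabelling of mutation ids
    relabel = {x: x * 7 + 3 for x in a | b}
    assert j == jaccard({relabel[x] for x in a}, {relabel[x] for x in b})
    if a and a == b:
        assert j == 1.0


# ---------------------------------------------------------------- filters
def _presence(counts, n_samples):
    """Matrix where column j is present in counts[j] of the samples."""
    mat = np.zeros((n_samples, len(counts)), dtype=np.int8)
    for j, c in enumerate(counts):
        mat[:c, j] = 1
    return mat


def test_biopsy_clonality_filters():
    mat = _presence([23, 12, 11, 1], n_samples=23)
    kept = subclonal_filter(mat, "present_in_all_samples")
    assert kept.tolist() == [1, 2, 3]  # only the everywhere-mutation dropped
    kept = subclonal_filter(mat, "present_in_more_than_half_of_samples")
    assert kept.tolist() == [2, 3]  # 12 > 11.5 excluded, 11 <= 11.5 retained
    with pytest.raises(ValueError):
        subclonal_filter(mat, "no_such_mode")


def test_whole_tumour_clonal_filter_drops_fixed_mutations():
    # hand-built tumour: seed (1 clonal mutation) -> two alive daughters
    tum = Tumour(
        config=SimulationConfig(push_rate=0.0, mutation_rate=1.0, target_size=2),
        side=7,
        centre=(3, 3),
        generation=1,
        n_pushes=0,
        parent=np.array([-1, 0, 0]),
        birth_gen=np.array([0, 1, 1]),
        mut_start=np.array([0, 1, 3]),
        mut_count=np.array([1, 2, 1]),
        alive=np.array([False, True, True]),
        pos=np.array([24, 24, 25]),
        lattice=np.full(49, -1),
    )
    kept = subclonal_filter(tum, "whole_tumour_clonal")
    assert kept.tolist() == [1, 2, 3]  # mutation 0 (in every cell) excluded


# ---------------------------------------------------------------- pair tables
@pytest.fixture(scope="module")
def small_records():
    tum = grow_tumour(SimulationConfig(push_rate=0.5, mutation_rate=10.0, target_size=2**10, seed=8))
    rng = np.random.default_rng(1)
    samples = random_square_samples(tum, 16, 30, rng)
    ordered = jaccard_distance_table(samples, tumour=tum, pairing="ordered")
    unordered = jaccard_distance_table(samples, tumour=tum, pairing="unordered")
    return ordered, unordered


def test_pair_counts_and_symmetry(small_records):
    ordered, unordered = small_records
    assert len(ordered) == 30 * 29
    assert len(unordered) == 30 * 29 // 2
    key = ordered.set_index(["sample_i", "sample_j"]).jaccard
    for (i, j), val in key.items():
        assert key.loc[(j, i)] == val
    assert ((ordered.jaccard >= 0) & (ordered.jaccard <= 1)).all()


def test_invalid_inputs_rejected():
    with pytest.raises(ValueError):
        jaccard_distance_table([], tumour=None, pairing="diagonal")
    with pytest.raises(ValueError):
        jaccard_distance_table([], tumour=None, presence=None)


# ---------------------------------------------------------------- trends
def test_null_construction_has_no_correlation(rng):
    n = 10_000
    records = pd.DataFrame(
        {
            "sample_i": np.zeros(n, dtype=int),
            "sample_j": np.ones(n, dtype=int),
            "jaccard": rng.random(n),
            "distance": rng.random(n) * 100 + 10,
            "non_overlapping": True,
        }
    )
    binned, trend = distance_trend_summary(records)
    assert abs(trend.pearson_r) < 0.05
    assert not trend.degenerate
    assert binned.n_pairs.sum() == n


def test_degenerate_constant_jaccard_flagged(rng):
    records = pd.DataFrame(
        {
            "sample_i": 0,
            "sample_j": 1,
            "jaccard": 0.5,
            "distance": rng.random(100) * 10 + 5,
            "non_overlapping": True,
        }
    )
    _, trend = distance_trend_summary(records)
    assert trend.degenerate and np.isnan(trend.pearson_r)


# ---------------------------------------------------------------- biopsy tables
def test_biopsy_table_distance_normalisation_and_validation():
    presence = pd.DataFrame(
        [[1, 0, 1], [1, 1, 0], [1, 1, 1]],
        index=pd.Index(["a", "b", "c"], name="sample_id"),
    )
    coords = pd.DataFrame({"x": [0.0, 3.0, 0.0], "y": [0.0, 0.0, 6.0]},
                          index=presence.index)
    table = BiopsyTable(presence, coords=coords)
    dm = table.pairwise_distances(normalize=True)
    assert dm.max() == 100.0 and np.allclose(np.diag(dm), 0) and np.allclose(dm, dm.T)
    with pytest.raises(ValueError):
        BiopsyTable(presence * 2, coords=coords)
    with pytest.raises(ValueError):
        BiopsyTable(presence)
    records = table.jaccard_records(filter_mode="present_in_all_samples")
    assert len(records) == 3
    # universal mutation 0 removed: pair (a,b) shares nothing of {1,2}
    ab = records[(records.sample_i == "a") & (records.sample_j == "b")].jaccard.iloc[0]
    assert ab == 0.0
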