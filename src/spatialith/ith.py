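"""Jaccard-index intra-tumour heterogeneity versus sampling distance.

The Jaccard index of two samples' mutation sets, J(A, B) = |A∩B| / |A∪B|,
is the similarity measure: 1 means identical mutation composition, 0 means
disjoint. ITH is inversely proportional to J, so the central quantity is how
J decays with the Euclidean distance between sample centres.

Clonal mutations (carried by every cell, or — for biopsy tables where purity
blurs clonality — present in all or in more than half of the samples) add no
spatial signal and only compress J toward 1, so they are filtered out before
comparison; the analysis runs on sub-clonal mutations.

Sample mutation sets are presence-based (a mutation is in the set if any
member cell carries it); an optional within-sample frequency cut can be
applied via ``min_within_frequency``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .growth import Tumour
from .mutations import subtree_carrier_counts, _expand_ranges
from .sampling import Sample, non_overlapping, sample_distance

__all__ = [
    "FILTER_WHOLE_TUMOUR_CLONAL",
    "FILTER_PRESENT_IN_ALL",
    "FILTER_PRESENT_IN_MORE_THAN_HALF",
    "jaccard",
    "sample_mutation_matrix",
    "subclonal_filter",
    "jaccard_distance_table",
    "distance_trend_summary",
    "TrendSummary",
    "BiopsyTable",
]

FILTER_WHOLE_TUMOUR_CLONAL = "whole_tumour_clonal"
FILTER_PRESENT_IN_ALL = "present_in_all_samples"
FILTER_PRESENT_IN_MORE_THAN_HALF = "present_in_more_than_half_of_samples"


def jaccard(a, b) -> float:
    """|A∩B| / |A∪B| for two mutation sets; both empty -> 0 by convention
    (after sub-clonal filtering, two uninformative samples are maximally
    dissimilar, not identical)."""
    sa, sb = set(a), set(b)
    union = len(sa | sb)
    if union == 0:
        return 0.0
    return len(sa & sb) / union


def sample_mutation_matrix(
    tumour: Tumour,
    samples: list[Sample],
    min_within_frequency: float = 0.0,
) -> sp.csr_matrix:
    """Boolean presence matrix (n_samples x n_mutations, global mutation-id
    columns): entry (i, j) is true when mutation j is carried by at least one
    member cell of sample i (or by a within-sample fraction >=
    ``min_within_frequency`` when that cut is requested)."""
    n_mut = tumour.n_mutations
    indptr = [0]
    indices = []
    for s in samples:
        cnt = subtree_carrier_counts(tumour, s.cell_ids)
        thresh = max(1, int(np.ceil(min_within_frequency * s.size)))
        sel = np.flatnonzero((tumour.mut_count > 0) & (cnt >= thresh))
        ids = _expand_ranges(tumour.mut_start[sel], tumour.mut_count[sel])
        indices.append(ids)
        indptr.append(indptr[-1] + ids.shape[0])
    data = np.ones(indptr[-1], dtype=np.int64)
    return sp.csr_matrix(
        (data, np.concatenate(indices) if indices else np.empty(0, dtype=np.int64), np.asarray(indptr)),
        shape=(len(samples), n_mut),
    )


def clonal_mutation_ids(tumour: Tumour) -> np.ndarray:
    """Mutations carried by every alive cell (whole-tumour clonal)."""
    alive = tumour.alive_ids()
    cnt = subtree_carrier_counts(tumour, alive)
    sel = np.flatnonzero((tumour.mut_count > 0) & (cnt == alive.size))
    return _expand_ranges(tumour.mut_start[sel], tumour.mut_count[sel])


def subclonal_filter(obj, mode: str, presence: sp.csr_matrix | None = None) -> np.ndarray:
    """Return the retained (sub-clonal) mutation-id universe under ``mode``.

    * ``whole_tumour_clonal`` — ``obj`` is a :class:`Tumour`; mutations with
      whole-tumour cell fraction exactly 1 are excluded.
    * ``present_in_all_samples`` / ``present_in_more_than_half_of_samples`` —
      ``obj`` is a samples x mutations presence matrix (scipy sparse, dense
      array or :class:`BiopsyTable`); columns present in all, respectively in
      strictly more than half, of the samples are excluded. Returned ids are
      column indices (or column labels for a BiopsyTable).
    """
    if mode == FILTER_WHOLE_TUMOUR_CLONAL:
        if not isinstance(obj, Tumour):
            raise TypeError("whole_tumour_clonal filtering needs a Tumour")
        clonal = clonal_mutation_ids(obj)
        keep = np.ones(obj.n_mutations, dtype=bool)
        keep[clonal] = False
        return np.flatnonzero(keep)
    if mode not in (FILTER_PRESENT_IN_ALL, FILTER_PRESENT_IN_MORE_THAN_HALF):
        raise ValueError(f"unknown filter mode {mode!r}")
    if isinstance(obj, BiopsyTable):
        counts = obj.presence.to_numpy().sum(axis=0)
        n = obj.presence.shape[0]
        keep = counts < n if mode == FILTER_PRESENT_IN_ALL else counts <= n / 2.0
        return obj.presence.columns.to_numpy()[keep]
    mat = obj if presence is None else presence
    if sp.issparse(mat):
        counts = np.asarray(mat.sum(axis=0)).ravel()
        n = mat.shape[0]
    else:
        mat = np.asarray(mat)
        counts = mat.sum(axis=0)
        n = mat.shape[0]
    keep = counts < n if mode == FILTER_PRESENT_IN_ALL else counts <= n / 2.0
    return np.flatnonzero(keep)


def _pairwise_jaccard(presence: sp.csr_matrix) -> np.ndarray:
    """Dense n x n Jaccard matrix from a sparse presence matrix."""
    presence = presence.astype(np.int64)
    inter = (presence @ presence.T).toarray()
    sizes = np.asarray(presence.sum(axis=1)).ravel()
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        jac = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    return jac


def jaccard_distance_table(
    samples: list[Sample],
    tumour: Tumour | None = None,
    presence: sp.csr_matrix | None = None,
    filter_mode: str | None = None,
    pairing: str = "ordered",
    min_within_frequency: float = 0.0,
) -> pd.DataFrame:
    """Pairwise Jaccard records for a sample set.

    One row per ordered pair (n(n-1) rows, the default) or per unordered
    pair (n(n-1)/2 rows). Columns: sample_i, sample_j, jaccard, distance,
    non_overlapping. ``filter_mode`` restricts the mutation universe before
    comparison (see :func:`subclonal_filter`).
    """
    if pairing not in ("ordered", "unordered"):
        raise ValueError(f"pairing must be 'ordered' or 'unordered', got {pairing!r}")
    if presence is None:
        if tumour is None:
            raise ValueError("need a tumour or a precomputed presence matrix")
        presence = sample_mutation_matrix(tumour, samples, min_within_frequency)
    if filter_mode is not None:
        if filter_mode == FILTER_WHOLE_TUMOUR_CLONAL:
            keep = subclonal_filter(tumour, filter_mode)
        else:
            keep = subclonal_filter(presence, filter_mode)
        presence = presence[:, keep]
    jac = _pairwise_jaccard(presence)
    n = len(samples)
    centres = np.asarray([s.centre for s in samples], dtype=float)
    diff = centres[:, None, :] - centres[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    los = np.asarray([s.bounds()[0] for s in samples])
    his = np.asarray([s.bounds()[1] for s in samples])
    disjoint = (
        (his[:, None, :] <= los[None, :, :]) | (his[None, :, :] <= los[:, None, :])
    ).any(axis=2)
    iu, ju = np.triu_indices(n, k=1)
    if pairing == "ordered":
        i = np.concatenate([iu, ju])
        j = np.concatenate([ju, iu])
    else:
        i, j = iu, ju
    ids = np.asarray([s.sample_id for s in samples])
    return pd.DataFrame(
        {
            "sample_i": ids[i],
            "sample_j": ids[j],
            "jaccard": jac[i, j],
            "distance": dist[i, j],
            "non_overlapping": disjoint[i, j],
        }
    )


@dataclass(frozen=True)
class TrendSummary:
    """Pearson correlation of Jaccard index against centre distance."""

    pearson_r: float
    p_value: float
    n_pairs: int
    degenerate: bool = False


def distance_trend_summary(
    records: pd.DataFrame,
    n_bins: int = 20,
    non_overlapping_only: bool = True,
) -> tuple[pd.DataFrame, TrendSummary]:
    """Binned mean/median Jaccard and the J-vs-distance Pearson correlation.

    Bins are ``n_bins`` equal-width intervals from the minimum non-overlapping
    distance to the maximum observed distance. Degenerate inputs (constant J
    or constant distance) yield ``TrendSummary(nan, nan, n, degenerate=True)``.
    """
    df = records[records["non_overlapping"]] if non_overlapping_only else records
    if len(df) < 3:
        raise ValueError("need >= 3 records with distinct distances")
    d = df["distance"].to_numpy()
    j = df["jaccard"].to_numpy()
    edges = np.linspace(d.min(), d.max(), n_bins + 1)
    which = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    binned = pd.DataFrame(
        {
            "bin_low": edges[:-1],
            "bin_high": edges[1:],
            "mean_jaccard": [
                j[which == b].mean() if (which == b).any() else np.nan for b in range(n_bins)
            ],
            "median_jaccard": [
                np.median(j[which == b]) if (which == b).any() else np.nan for b in range(n_bins)
            ],
            "n_pairs": [(which == b).sum() for b in range(n_bins)],
        }
    )
    if np.ptp(j) == 0 or np.ptp(d) == 0:
        return binned, TrendSummary(float("nan"), float("nan"), len(df), degenerate=True)
    r, p = stats.pearsonr(j, d)
    return binned, TrendSummary(float(r), float(p), len(df))


class BiopsyTable:
    """Generic multi-region biopsy data: binary mutation presence across
    samples plus per-sample coordinates (or a precomputed distance matrix).

    ``presence`` is a samples x mutations 0/1 DataFrame; ``coords`` a
    DataFrame indexed by sample id with columns x, y (z optional). Distances
    are Euclidean between sample coordinates and, following multi-region
    study convention, can be normalised so the largest pairwise distance is
    100 (the diameter of the sampled tissue).
    """

    def __init__(
        self,
        presence: pd.DataFrame,
        coords: pd.DataFrame | None = None,
        distances: pd.DataFrame | None = None,
    ):
        if coords is None and distances is None:
            raise ValueError("need sample coordinates or a distance matrix")
        vals = presence.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("presence entries must be binary")
        self.presence = presence.astype(np.int8)
        self.coords = coords
        if distances is not None:
            dm = distances.to_numpy(dtype=float)
            if not np.allclose(dm, dm.T) or not np.allclose(np.diag(dm), 0):
                raise ValueError("distance matrix must be symmetric with zero diagonal")
        self.distances = distances

    @classmethod
    def from_files(
        cls,
        presence_path,
        coords_path=None,
        distances_path=None,
    ) -> "BiopsyTable":
        """Read a long-format presence TSV (sample_id, mutation_id) plus a
        coordinates TSV (sample_id, x, y[, z]) or a distance-matrix TSV."""
        long = pd.read_csv(presence_path, sep="\t")
        presence = (
            pd.crosstab(long["sample_id"], long["mutation_id"]).clip(upper=1)
        )
        coords = distances = None
        if coords_path is not None:
            coords = pd.read_csv(coords_path, sep="\t").set_index("sample_id")
            coords = coords.loc[presence.index]
        if distances_path is not None:
            distances = pd.read_csv(distances_path, sep="\t", index_col=0)
        return cls(presence, coords=coords, distances=distances)

    @property
    def n_samples(self) -> int:
        return int(self.presence.shape[0])

    def pairwise_distances(self, normalize: bool = True) -> np.ndarray:
        if self.distances is not None:
            dm = self.distances.to_numpy(dtype=float)
        else:
            xy = self.coords.to_numpy(dtype=float)
            diff = xy[:, None, :] - xy[None, :, :]
            dm = np.sqrt((diff**2).sum(axis=2))
        if normalize and dm.max() > 0:
            dm = dm * (100.0 / dm.max())
        return dm

    def jaccard_records(
        self, filter_mode: str | None = FILTER_PRESENT_IN_MORE_THAN_HALF,
        normalize_distance: bool = True,
    ) -> pd.DataFrame:
        """Unordered pairwise Jaccard records over the (filtered) mutation
        universe, with (normalised) sampling distances."""
        mat = self.presence
        if filter_mode is not None:
            keep = subclonal_filter(self, filter_mode)
            mat = mat[list(keep)]
        presence = sp.csr_matrix(mat.to_numpy())
        jac = _pairwise_jaccard(presence)
        dm = self.pairwise_distances(normalize=normalize_distance)
        iu, ju = np.triu_indices(self.n_samples, k=1)
        sids = self.presence.index.to_numpy()
        return pd.DataFrame(
            {
                "sample_i": sids[iu],
                "sample_j": sids[ju],
                "jaccard": jac[iu, ju],
                "distance": dm[iu, ju],
                "non_overlapping": True,
            }
        )

    def distance_correlation(
        self, filter_mode: str | None = FILTER_PRESENT_IN_MORE_THAN_HALF
    ) -> TrendSummary:
        records = self.jaccard_records(filter_mode=filter_mode)
        _, trend = distance_trend_summary(records, n_bins=10)
        return trend
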