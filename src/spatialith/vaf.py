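"""Cumulative VAF curves, neutral-model mutation-rate inference, and a
KS-style linearity diagnostic.

Under neutral exponential growth the site-frequency spectrum of a pure-birth
tumour follows a 1/f power law, so the cumulative count of mutations at
frequency >= f is linear in 1/f:

    M(f) = (mu / beta) * (1/f - 1/f_max)

The slope of ordinary least squares of M against 1/f therefore estimates the
effective mutation rate mu/beta (the per-division rate scaled by the
birth/death structure; with no death, exactly the per-daughter rate lambda).

Frequencies enter the regression in the heterozygous-diploid VAF convention
v = f_c / 2 with f_max = 0.5: with each daughter drawing Poisson(lambda)
mutations, the generation-g daughters contribute lambda * 2**g mutations at
v = 2**-(g+1), giving M(v) = lambda * (1/v - 2) — the fitted slope is then
lambda itself. (The cell-fraction convention, slope 2*lambda, is available.)

Deviation from linearity is quantified by a Kolmogorov–Smirnov-style
distance: observed and fitted curves are normalised by the maximum observed
M over the fitted points, and D is the maximum absolute difference, clipped
to [0, 1]. Low push rates and small samples inflate D; a large D means the
slope estimate should not be trusted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .mutations import CELL_FRACTION, DIPLOID_VAF, FrequencySpectrum

__all__ = [
    "detection_filter",
    "CumulativeCurve",
    "cumulative_vaf",
    "truncate_low_frequency",
    "ks_distance",
    "CumulativeVAFModel",
    "VAFLinearFit",
]


def detection_filter(spectrum: FrequencySpectrum, limit: float = 0.01) -> FrequencySpectrum:
    """Drop mutations below the detection threshold (inclusive retention:
    frequency == limit is kept). The limit is interpreted in the spectrum's
    own convention; the standard 0.01 cut applies to cell fractions."""
    if not (0.0 <= limit < 1.0):
        raise ValueError("detection limit must be in [0, 1)")
    if limit == 0.0:
        return spectrum
    keep = spectrum.fractions >= limit
    return replace(
        spectrum,
        mutation_ids=spectrum.mutation_ids[keep],
        fractions=spectrum.fractions[keep],
    )


@dataclass(frozen=True)
class CumulativeCurve:
    """Points (1/v, M(v)) of a cumulative mutation-frequency curve.

    ``inv_freq`` is ascending (high frequency first); ``counts[i]`` is the
    number of mutations with frequency >= the i-th distinct frequency. M is
    non-decreasing in 1/v by construction.
    """

    inv_freq: np.ndarray
    counts: np.ndarray
    convention: str
    f_max: float
    truncated: bool = False

    def __post_init__(self) -> None:
        if np.any(np.diff(self.inv_freq) <= 0):
            raise ValueError("inv_freq must be strictly increasing")
        if np.any(np.diff(self.counts) < 0):
            raise ValueError("cumulative counts must be non-decreasing")

    def __len__(self) -> int:
        return int(self.inv_freq.shape[0])

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({"inv_freq": self.inv_freq, "cumulative_count": self.counts})


def cumulative_vaf(
    spectrum: FrequencySpectrum, convention: str = DIPLOID_VAF
) -> CumulativeCurve:
    """Build the cumulative curve M(v) = #{mutations with frequency >= v}
    over the distinct observed frequencies.

    With ``convention="diploid_vaf"`` (default) cell fractions are halved and
    f_max = 0.5; with ``"cell_fraction"`` frequencies are used as-is and
    f_max = 1.
    """
    if len(spectrum) == 0:
        raise ValueError("empty frequency spectrum")
    if convention == DIPLOID_VAF:
        v = (
            spectrum.fractions / 2.0
            if spectrum.convention == CELL_FRACTION
            else spectrum.fractions
        )
        f_max = 0.5
    elif convention == CELL_FRACTION:
        if spectrum.convention != CELL_FRACTION:
            raise ValueError("cannot widen a diploid spectrum back to cell fractions")
        v = spectrum.fractions
        f_max = 1.0
    else:
        raise ValueError(f"unknown convention {convention!r}")
    distinct, cnt = np.unique(v, return_counts=True)  # ascending v
    desc = distinct[::-1]
    m = np.cumsum(cnt[::-1])
    return CumulativeCurve(
        inv_freq=1.0 / desc, counts=m.astype(np.int64), convention=convention, f_max=f_max
    )


def truncate_low_frequency(curve: CumulativeCurve, n_points: int) -> CumulativeCurve:
    """Drop the ``n_points`` lowest-frequency (largest 1/v) points — the tail
    dominated by the detection limit — before regression."""
    if n_points == 0:
        return curve
    if n_points < 0:
        raise ValueError("n_points must be >= 0")
    if len(curve) <= n_points:
        raise ValueError(
            f"cannot drop {n_points} points from a {len(curve)}-point curve"
        )
    return replace(
        curve,
        inv_freq=curve.inv_freq[:-n_points],
        counts=curve.counts[:-n_points],
        truncated=True,
    )


def ks_distance(curve: CumulativeCurve, slope: float, intercept: float) -> float:
    """Maximum absolute difference between the observed cumulative curve and
    the fitted line, both normalised by the maximum observed count over the
    fitted points; clipped to [0, 1]."""
    m_max = float(curve.counts.max())
    if m_max <= 0:
        raise ValueError("degenerate curve: no mutations")
    fitted = slope * curve.inv_freq + intercept
    d = np.abs(curve.counts - fitted).max() / m_max
    return float(np.clip(d, 0.0, 1.0))


@dataclass(frozen=True)
class VAFLinearFit:
    """Results of fitting the neutral linear model to a cumulative curve.

    ``mutation_rate`` is the OLS slope of M against 1/v — the effective
    mutation rate mu/beta. ``ks_dist`` in [0, 1] is the linearity diagnostic.
    """

    mutation_rate: float
    intercept: float
    stderr: float
    rvalue: float
    ks_dist: float
    n_points: int
    convention: str
    f_max: float

    def summary(self) -> str:
        lines = [
            "Neutral cumulative-VAF linear fit",
            "=" * 46,
            f"{'frequency convention':<30}{self.convention:>16}",
            f"{'f_max':<30}{self.f_max:>16.3f}",
            f"{'points fitted':<30}{self.n_points:>16d}",
            "-" * 46,
            f"{'effective mutation rate':<30}{self.mutation_rate:>16.4f}",
            f"{'slope std. error':<30}{self.stderr:>16.4f}",
            f"{'intercept':<30}{self.intercept:>16.4f}",
            f"{'R':<30}{self.rvalue:>16.4f}",
            f"{'KS distance':<30}{self.ks_dist:>16.4f}",
            "=" * 46,
        ]
        return "\n".join(lines)


class CumulativeVAFModel:
    """OLS of the cumulative mutation count against inverse frequency.

    Construct from a prepared :class:`CumulativeCurve`, or from a raw
    :class:`FrequencySpectrum` via :meth:`from_spectrum`, which applies the
    standard pipeline (detection filter on cell fractions, conversion to the
    requested frequency convention, low-frequency truncation). ``fit()``
    returns a :class:`VAFLinearFit`.

    The intercept is free rather than pinned to -(mu/beta)/f_max: the free
    intercept absorbs detection-limit truncation effects and the slope alone
    carries the rate estimate.
    """

    def __init__(self, curve: CumulativeCurve):
        if len(curve) < 2:
            raise ValueError("need at least 2 curve points to fit")
        if np.ptp(curve.inv_freq) == 0:
            raise ValueError("zero variance in 1/v")
        self.curve = curve

    @classmethod
    def from_spectrum(
        cls,
        spectrum: FrequencySpectrum,
        detection_limit: float = 0.01,
        truncation_points: int = 3,
        convention: str = DIPLOID_VAF,
    ) -> "CumulativeVAFModel":
        filtered = detection_filter(spectrum, detection_limit)
        curve = cumulative_vaf(filtered, convention=convention)
        if truncation_points and len(curve) > truncation_points + 1:
            curve = truncate_low_frequency(curve, truncation_points)
        return cls(curve)

    def fit(self) -> VAFLinearFit:
        res = stats.linregress(self.curve.inv_freq, self.curve.counts.astype(float))
        d = ks_distance(self.curve, res.slope, res.intercept)
        return VAFLinearFit(
            mutation_rate=float(res.slope),
            intercept=float(res.intercept),
            stderr=float(res.stderr),
            rvalue=float(res.rvalue),
            ks_dist=d,
            n_points=len(self.curve),
            convention=self.curve.convention,
            f_max=self.curve.f_max,
        )
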