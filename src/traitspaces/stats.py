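"""Comparison statistics for occupancy measures.

Four pieces of machinery used throughout the simulation study and the
group comparisons:

* scaling of measure values into a common, unitless change score
  (:func:`scale_measure_values`),
* histogram-overlap quantification via the Bhattacharyya coefficient
  (:func:`bhattacharyya_coefficient`),
* pairwise Pearson correlation between measures across many spaces
  (:func:`pairwise_measure_correlations`), and
* a one-way ANOVA F statistic computed from sums of squares
  (:func:`one_way_anova_f`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ScaledValues",
    "OverlapSummary",
    "AnovaResult",
    "scale_measure_values",
    "bhattacharyya_coefficient",
    "pairwise_measure_correlations",
    "one_way_anova_f",
]


@dataclass(frozen=True)
class ScaledValues:
    """Scaled change scores for one measure under one reduction scenario."""

    scaled: np.ndarray
    normalizer: float
    n_dropped: int  # pairs dropped because either value was invalid (NaN)


def scale_measure_values(full_values, reduced_values,
                         normalizer: float | None = None) -> ScaledValues:
    """Scale reduced-space measure values against their unreduced baseline.

    ``scaled_i = (reduced_i - full_i) / max_i |full_i|``: 0 means the
    reduction had no effect, the sign gives the direction of change, and
    the normaliser (the maximum absolute unreduced value across the
    paired replicates, or an externally supplied one, e.g. computed over
    a whole space type) makes measures with different units comparable.
    Pairs where either value is invalid (NaN) are dropped and counted.
    """
    full = np.asarray(full_values, dtype=float)
    red = np.asarray(reduced_values, dtype=float)
    if full.shape != red.shape:
        raise ValueError("full and reduced value vectors must be paired (equal length)")
    ok = np.isfinite(full) & np.isfinite(red)
    n_dropped = int((~ok).sum())
    full, red = full[ok], red[ok]
    if full.size == 0:
        warnings.warn("all replicate pairs invalid; empty scaled result", stacklevel=2)
        return ScaledValues(np.empty(0), math.nan, n_dropped)
    norm = float(np.max(np.abs(full))) if normalizer is None else float(normalizer)
    if norm == 0 or not math.isfinite(norm):
        return ScaledValues(np.full(full.shape, math.nan), norm, n_dropped)
    return ScaledValues((red - full) / norm, norm, n_dropped)


@dataclass(frozen=True)
class OverlapSummary:
    """Bhattacharyya coefficient between two samples over shared bins."""

    bc: float
    n_x: int
    n_y: int
    bin_edges: np.ndarray
    degenerate: bool = False  # zero pooled range, BC = 1 by convention


def bhattacharyya_coefficient(x, y, n_bins: int | None = None) -> OverlapSummary:
    """Histogram overlap of two samples: ``BC = sum_b sqrt(p_b * q_b)``.

    Equal-width bins span the pooled range of both samples; the default
    bin count is ``ceil(sqrt(n_x + n_y))``.  BC is 1 for identical
    distributions and 0 for distributions with disjoint support.  If the
    pooled range is zero (every value identical), BC is 1 by convention
    and the result is flagged degenerate.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must contain at least one finite value")
    lo = min(x.min(), y.min())
    hi = max(x.max(), y.max())
    if lo == hi:
        return OverlapSummary(1.0, x.size, y.size, np.array([lo, hi]), degenerate=True)
    if n_bins is None:
        n_bins = int(np.ceil(np.sqrt(x.size + y.size)))
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    edges = np.linspace(lo, hi, n_bins + 1)
    p = np.histogram(x, bins=edges)[0] / x.size
    q = np.histogram(y, bins=edges)[0] / y.size
    bc = float(np.sqrt(p * q).sum())
    return OverlapSummary(min(bc, 1.0), x.size, y.size, edges)


def pairwise_measure_correlations(values: pd.DataFrame,
                                  min_periods: int = 3) -> pd.DataFrame:
    """Pairwise Pearson correlation between measure columns.

    ``values`` is a wide table (rows = spaces, columns = measures).
    Columns are standardised (zero mean, unit variance) first — Pearson r
    is invariant to this, but the standardised table is also what gets
    serialised — and correlations use pairwise-complete observations so
    that a measure that is invalid on some spaces (NaN) does not empty
    the table.  Constant columns yield NaN for their pairs.
    """
    values = pd.DataFrame(values).astype(float).replace([np.inf, -np.inf], np.nan)
    # prescale by the column max so that extreme magnitudes (e.g. ellipsoid
    # volumes near the float underflow limit) survive the variance computation
    values = values / values.abs().max().replace(0.0, 1.0)
    std = values.std(ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - values.mean()) / std
    corr = z.corr(method="pearson", min_periods=min_periods)
    np.fill_diagonal(corr.values, np.where(std.to_numpy() > 0, 1.0, np.nan))
    return corr


@dataclass(frozen=True)
class AnovaResult:
    """Classical one-way ANOVA decomposition."""

    f: float
    p: float
    df_between: int
    df_within: int
    ss_between: float
    ss_within: float


def one_way_anova_f(values, groups) -> AnovaResult:
    """One-way ANOVA F from explicit sums of squares.

    ``F = (SSB / df_b) / (SSW / df_w)`` with SSB the between-group and
    SSW the within-group sum of squares; the p-value comes from the F
    distribution.  Zero within-group variance with non-zero between-group
    variance gives ``F = +inf`` (p = 0).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have equal length")
    ok = np.isfinite(values)
    values, groups = values[ok], groups[ok]
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    grand = values.mean()
    ssb = ssw = 0.0
    for lab in labels:
        v = values[groups == lab]
        if v.size < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 values")
        ssb += v.size * (v.mean() - grand) ** 2
        ssw += ((v - v.mean()) ** 2).sum()
    df_b = len(labels) - 1
    df_w = values.size - len(labels)
    if ssw == 0:
        f = math.inf if ssb > 0 else 0.0
    else:
        f = (ssb / df_b) / (ssw / df_w)
    p = float(sps.f.sf(f, df_b, df_w)) if math.isfinite(f) else 0.0
    return AnovaResult(float(f), p, df_b, df_w, float(ssb), float(ssw))
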