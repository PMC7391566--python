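"""Space occupancy measures.

Eight built-in measures summarise how a set of observations occupies a
Euclidean trait space, grouped into three categories:

* **size** — how much space is occupied: mean Euclidean distance from the
  centroid (FDis without abundance weights), sum of per-dimension sample
  variances, sum of per-dimension ranges, and the volume of the ellipsoid
  with semi-axes equal to the square roots of the covariance eigenvalues.
* **density** — how packed the observations are: average minimum spanning
  tree (MST) edge length, MST edge-length evenness (FEve without
  abundance weights), and mean nearest-neighbour distance.
* **position** — where the group sits: average displacement, the ratio of
  summed distances from the coordinate origin to summed distances from
  the group centroid (1 when the group is centred on the origin).

All measures assume a Euclidean, isotropic space.  Each returns a
:class:`MeasureValue`; degenerate inputs (too few observations, a
rank-deficient covariance) yield an invalid marker with a reason instead
of raising, mirroring how such cells are reported as NA in practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln

from .simulator import TraitSpace

__all__ = [
    "MeasureValue",
    "SpanningTree",
    "distance_matrix",
    "centroid",
    "mean_distance_from_centroid",
    "sum_of_variances",
    "sum_of_ranges",
    "ellipsoid_volume",
    "minimum_spanning_tree",
    "mst_average_distance",
    "mst_evenness",
    "mean_nearest_neighbour_distance",
    "average_displacement",
    "measure_registry",
    "apply_measures",
]

#: Eigenvalues at or below this floor mark the covariance as rank deficient.
EIGENVALUE_FLOOR = 1e-12


@dataclass(frozen=True)
class MeasureValue:
    """One measure evaluated on one (possibly reduced) trait space."""

    name: str
    category: str  # size | density | position
    value: float
    valid: bool = True
    reason: str | None = None
    n_obs_used: int = 0

    def __float__(self) -> float:
        return self.value if self.valid else math.nan


def _invalid(name: str, category: str, reason: str, n: int) -> MeasureValue:
    return MeasureValue(name, category, math.nan, valid=False, reason=reason, n_obs_used=n)


def _as_matrix(space) -> np.ndarray:
    if isinstance(space, TraitSpace):
        return space.data
    x = np.asarray(space, dtype=float)
    return x[:, None] if x.ndim == 1 else x


def distance_matrix(space) -> np.ndarray:
    """Full symmetric matrix of pairwise Euclidean distances."""
    x = _as_matrix(space)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 observations for pairwise distances")
    return squareform(pdist(x))


def centroid(space) -> np.ndarray:
    """Per-dimension arithmetic mean of the observations."""
    x = _as_matrix(space)
    if x.shape[0] < 1:
        raise ValueError("empty trait space has no centroid")
    return x.mean(axis=0)


def mean_distance_from_centroid(space, **_) -> MeasureValue:
    """Mean Euclidean distance of observations from their centroid (size)."""
    x = _as_matrix(space)
    n = x.shape[0]
    if n < 1:
        return _invalid("mean_distance_from_centroid", "size", "empty space", 0)
    val = float(np.linalg.norm(x - x.mean(axis=0), axis=1).mean())
    return MeasureValue("mean_distance_from_centroid", "size", val, n_obs_used=n)


def sum_of_variances(space, **_) -> MeasureValue:
    """Sum of per-dimension sample variances, n-1 denominator (size)."""
    x = _as_matrix(space)
    n = x.shape[0]
    if n < 2:
        return _invalid("sum_of_variances", "size", "sample variance needs n >= 2", n)
    val = float(x.var(axis=0, ddof=1).sum())
    return MeasureValue("sum_of_variances", "size", val, n_obs_used=n)


def sum_of_ranges(space, **_) -> MeasureValue:
    """Sum of per-dimension ranges max - min (size)."""
    x = _as_matrix(space)
    n = x.shape[0]
    if n < 1:
        return _invalid("sum_of_ranges", "size", "empty space", 0)
    val = float((x.max(axis=0) - x.min(axis=0)).sum())
    return MeasureValue("sum_of_ranges", "size", val, n_obs_used=n)


def ellipsoid_volume(space, **_) -> MeasureValue:
    """Volume of the covariance ellipsoid (size).

    ``V = pi^(d/2) / Gamma(d/2 + 1) * prod_i sqrt(lambda_i)`` with
    ``lambda_i`` the eigenvalues of the sample covariance matrix
    (semi-axes ``sqrt(lambda_i)``).  Evaluated in log space so that very
    high-dimensional spaces underflow gracefully rather than overflow.
    When any eigenvalue falls at or below the numeric floor — notably
    when ``n <= d`` and the covariance is rank deficient — the volume is
    undefined and an invalid marker is returned ("curse of
    multidimensionality").
    """
    x = _as_matrix(space)
    n, d = x.shape
    if n < 2:
        return _invalid("ellipsoid_volume", "size", "covariance needs n >= 2", n)
    eigvals = np.linalg.eigvalsh(np.cov(x, rowvar=False).reshape(d, d))
    if eigvals[0] <= EIGENVALUE_FLOOR:
        return _invalid(
            "ellipsoid_volume", "size",
            "curse of multidimensionality: rank-deficient covariance", n,
        )
    log_vol = (d / 2) * math.log(math.pi) - gammaln(d / 2 + 1) + 0.5 * np.log(eigvals).sum()
    return MeasureValue("ellipsoid_volume", "size", float(np.exp(log_vol)), n_obs_used=n)


@dataclass(frozen=True)
class SpanningTree:
    """A spanning tree over ``n`` observations: ``n - 1`` edges ``(i, j, length)``."""

    edges: tuple[tuple[int, int, float], ...]
    n_obs: int

    @property
    def total_length(self) -> float:
        return float(sum(e[2] for e in self.edges))

    @property
    def edge_lengths(self) -> np.ndarray:
        return np.array([e[2] for e in self.edges])


def minimum_spanning_tree(dm: np.ndarray) -> SpanningTree:
    """Minimum spanning tree of a complete graph given its distance matrix.

    Kruskal's algorithm with edges sorted by (length, i, j) so that ties
    are broken by the lowest index pair and the result is deterministic
    across platforms.
    """
    dm = np.asarray(dm, dtype=float)
    n = dm.shape[0]
    if dm.ndim != 2 or dm.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if n < 2:
        raise ValueError("need at least 2 observations for a spanning tree")
    ii, jj = np.triu_indices(n, 1)
    w = dm[ii, jj]
    order = np.lexsort((jj, ii, w))
    parent = np.arange(n)

    def find(a: int) -> int:
        root = a
        while parent[root] != root:
            root = parent[root]
        while parent[a] != root:  # path compression
            parent[a], a = root, parent[a]
        return root

    edges: list[tuple[int, int, float]] = []
    for k in order:
        a, b = find(int(ii[k])), find(int(jj[k]))
        if a != b:
            parent[a] = b
            edges.append((int(ii[k]), int(jj[k]), float(w[k])))
            if len(edges) == n - 1:
                break
    return SpanningTree(tuple(edges), n)


def _mst_lengths(space, dm: np.ndarray | None) -> np.ndarray:
    if dm is None:
        dm = distance_matrix(space)
    return minimum_spanning_tree(dm).edge_lengths


def mst_average_distance(space, dm: np.ndarray | None = None,
                         mst_lengths: np.ndarray | None = None, **_) -> MeasureValue:
    """Total MST edge length divided by n - 1 (density)."""
    x = _as_matrix(space)
    n = x.shape[0]
    if n < 2:
        return _invalid("mst_average_distance", "density", "MST needs n >= 2", n)
    if mst_lengths is None:
        mst_lengths = _mst_lengths(space, dm)
    val = float(mst_lengths.mean())
    return MeasureValue("mst_average_distance", "density", val, n_obs_used=n)


def mst_evenness(space, dm: np.ndarray | None = None,
                 mst_lengths: np.ndarray | None = None, **_) -> MeasureValue:
    """Evenness of MST edge lengths, FEve without abundance weights (density).

    With partial edge weights ``PEW_l = EW_l / sum(EW)`` and
    ``s = 1 / (n - 1)``:  ``FEve = (sum_l min(PEW_l, s) - s) / (1 - s)``,
    bounded in [0, 1]; 1 means perfectly even edge lengths.
    """
    x = _as_matrix(space)
    n = x.shape[0]
    if n < 3:
        return _invalid("mst_evenness", "density", "evenness needs n >= 3", n)
    lengths = mst_lengths if mst_lengths is not None else _mst_lengths(space, dm)
    total = lengths.sum()
    if total <= 0:
        return _invalid("mst_evenness", "density", "all MST edges have zero length", n)
    s = 1.0 / (n - 1)
    val = float((np.minimum(lengths / total, s).sum() - s) / (1.0 - s))
    return MeasureValue("mst_evenness", "density", val, n_obs_used=n)


def mean_nearest_neighbour_distance(space, dm: np.ndarray | None = None, **_) -> MeasureValue:
    """Mean distance from each observation to its nearest neighbour (density)."""
    x = _as_matrix(space)
    n = x.shape[0]
    if n < 2:
        return _invalid("mean_nearest_neighbour_distance", "density",
                        "nearest neighbour needs n >= 2", n)
    if dm is None:
        dm = distance_matrix(space)
    d = dm.copy()
    np.fill_diagonal(d, np.inf)
    val = float(d.min(axis=1).mean())
    return MeasureValue("mean_nearest_neighbour_distance", "density", val, n_obs_used=n)


def average_displacement(space, **_) -> MeasureValue:
    """Summed distances from the origin over summed distances from the centroid.

    The reference point is the coordinate origin ``(0, ..., 0)`` — the
    centre of the trait space.  A value of 1 indicates the group centroid
    coincides with that centre; larger values indicate displacement
    (position).  Undefined when all observations coincide.
    """
    x = _as_matrix(space)
    n = x.shape[0]
    if n < 1:
        return _invalid("average_displacement", "position", "empty space", 0)
    denom = np.linalg.norm(x - x.mean(axis=0), axis=1).sum()
    if denom <= 0:
        return _invalid("average_displacement", "position",
                        "all observations coincide", n)
    val = float(np.linalg.norm(x, axis=1).sum() / denom)
    return MeasureValue("average_displacement", "position", val, n_obs_used=n)


class MeasureRegistry:
    """Registry mapping measure names to callables ``space -> MeasureValue``.

    The eight built-ins are pre-registered; user measures can be added
    with :meth:`register` (mirroring user-designed occupancy measures).
    """

    def __init__(self) -> None:
        self._measures: dict[str, tuple[str, Callable]] = {}

    def register(self, name: str, category: str, fn: Callable) -> None:
        if name in self._measures:
            raise ValueError(f"measure {name!r} is already registered")
        if category not in ("size", "density", "position"):
            raise ValueError("category must be one of size, density, position")
        self._measures[name] = (category, fn)

    def get(self, name: str) -> Callable:
        try:
            return self._measures[name][1]
        except KeyError:
            raise KeyError(f"unknown measure {name!r}; known: {self.list()}") from None

    def category(self, name: str) -> str:
        self.get(name)
        return self._measures[name][0]

    def list(self) -> list[str]:
        return list(self._measures)

    def __contains__(self, name: str) -> bool:
        return name in self._measures


measure_registry = MeasureRegistry()
for _name, _cat, _fn in [
    ("mean_distance_from_centroid", "size", mean_distance_from_centroid),
    ("sum_of_variances", "size", sum_of_variances),
    ("sum_of_ranges", "size", sum_of_ranges),
    ("ellipsoid_volume", "size", ellipsoid_volume),
    ("mst_average_distance", "density", mst_average_distance),
    ("mst_evenness", "density", mst_evenness),
    ("mean_nearest_neighbour_distance", "density", mean_nearest_neighbour_distance),
    ("average_displacement", "position", average_displacement),
]:
    measure_registry.register(_name, _cat, _fn)

#: Names of the eight built-in measures, in canonical order.
BUILTIN_MEASURES: tuple[str, ...] = tuple(measure_registry.list())

_DISTANCE_BASED = {"mst_average_distance", "mst_evenness", "mean_nearest_neighbour_distance"}


def apply_measures(space, measures: list[str] | None = None) -> list[MeasureValue]:
    """Evaluate several measures on one space, sharing the distance matrix.

    The pairwise distance matrix (and hence the MST it implies) is the
    expensive part for the density measures, so it is computed once here.
    """
    names = list(measures) if measures is not None else list(BUILTIN_MEASURES)
    dm = lengths = None
    n = _as_matrix(space).shape[0]
    if any(m in _DISTANCE_BASED for m in names) and n >= 2:
        dm = distance_matrix(space)
        if sum(m in ("mst_average_distance", "mst_evenness") for m in names) > 1:
            lengths = minimum_spanning_tree(dm).edge_lengths
    out = []
    for name in names:
        fn = measure_registry.get(name)
        if name in _DISTANCE_BASED:
            out.append(fn(space, dm=dm, mst_lengths=lengths))
        else:
            out.append(fn(space))
    return out
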