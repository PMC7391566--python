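"""Space-reduction algorithms.

Each algorithm removes a fixed fraction of observations from a trait
space to emulate a biological change, returning a boolean keep-mask:

* **random** — uniform removal: the null model, where occupancy should
  not change systematically.
* **size** — removal by distance from the centre of the space (the
  coordinate origin).  Direction ``maximum`` keeps the innermost points
  (contraction of the space); ``minimum`` keeps the outermost points
  (hollowing — the periphery survives, the interior empties).
* **density** — removal by pairwise distance: direction ``high`` accretes
  the members of the shortest pairs (a tightly packed, high-density
  subset); ``low`` accretes from the longest pairs (a sparse subset).
* **position** — removal by distance from the single furthest point from
  the centre: ``positive`` keeps the points closest to it (a displaced
  cluster); ``negative`` keeps the points furthest from it.

All reductions keep exactly ``round(fraction * n)`` observations.  The
separating radius/distance that achieves the target fraction is solved
directly from order statistics (equivalent to, but simpler and more
deterministic than, an iterative threshold search) and reported as
``threshold`` for interpretability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .simulator import TraitSpace
from .measures import _as_matrix

__all__ = [
    "ReductionResult",
    "reduce_random",
    "reduce_size",
    "reduce_density",
    "reduce_position",
    "reduce_space",
    "SCENARIOS",
]

#: The seven canonical reduction scenarios as (algorithm, direction) pairs.
SCENARIOS: tuple[tuple[str, str], ...] = (
    ("random", "none"),
    ("size", "maximum"),
    ("size", "minimum"),
    ("density", "high"),
    ("density", "low"),
    ("position", "positive"),
    ("position", "negative"),
)

_DIRECTIONS = {
    "random": ("none",),
    "size": ("maximum", "minimum"),
    "density": ("high", "low"),
    "position": ("positive", "negative"),
}


@dataclass(frozen=True)
class ReductionResult:
    """Outcome of one space reduction: which observations to keep."""

    keep_mask: np.ndarray
    algorithm: str
    direction: str
    target_fraction: float
    threshold: float | None = None  # solved radius rho or pair distance D
    seed: int | None = None  # random reduction only

    @property
    def n_kept(self) -> int:
        return int(self.keep_mask.sum())

    def apply(self, space: TraitSpace) -> TraitSpace:
        """Return the reduced trait space (kept rows only)."""
        return space.subset(self.keep_mask)


def _n_keep(n: int, fraction: float) -> int:
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    k = int(np.floor(fraction * n + 0.5))  # round half up, platform-stable
    if k < 1:
        raise ValueError(f"fraction {fraction} keeps no observation of {n}")
    if k >= n:
        raise ValueError(f"fraction {fraction} removes no observation of {n}")
    return k


def _mask(n: int, keep_idx: np.ndarray) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    mask[keep_idx] = True
    return mask


def _keep_by_rank(values: np.ndarray, k: int, keep_smallest: bool):
    """Keep the k smallest (or largest) values; ties broken by row index.

    Returns (mask, threshold) where the threshold is the midpoint of the
    two order statistics flanking the cut.
    """
    n = len(values)
    order = np.argsort(values, kind="stable")
    if not keep_smallest:
        order = order[::-1]
    keep = order[:k]
    sorted_vals = values[order]
    threshold = float((sorted_vals[k - 1] + sorted_vals[k]) / 2) if k < n else float(sorted_vals[-1])
    return _mask(n, keep), threshold


def reduce_random(space, fraction: float = 0.5, seed: int = 0) -> ReductionResult:
    """Keep ``round(fraction * n)`` observations uniformly at random."""
    x = _as_matrix(space)
    n = x.shape[0]
    k = _n_keep(n, fraction)
    rng = np.random.default_rng(seed)
    keep = rng.choice(n, size=k, replace=False)
    return ReductionResult(_mask(n, keep), "random", "none", fraction, seed=seed)


def reduce_size(space, fraction: float = 0.5, direction: str = "maximum",
                center: str = "origin") -> ReductionResult:
    """Keep observations by distance from the centre of the space.

    ``maximum`` keeps the closest points (removes the periphery: the
    space contracts); ``minimum`` keeps the farthest points (removes the
    interior: the space is hollowed out).  The centre defaults to the
    coordinate origin; ``center="centroid"`` supports user data that is
    not origin-centred.
    """
    if direction not in _DIRECTIONS["size"]:
        raise ValueError(f"size direction must be maximum or minimum, got {direction!r}")
    x = _as_matrix(space)
    k = _n_keep(x.shape[0], fraction)
    ref = x.mean(axis=0) if center == "centroid" else np.zeros(x.shape[1])
    dist = np.linalg.norm(x - ref, axis=1)
    mask, rho = _keep_by_rank(dist, k, keep_smallest=(direction == "maximum"))
    return ReductionResult(mask, "size", direction, fraction, threshold=rho)


def reduce_density(space, fraction: float = 0.5, direction: str = "high") -> ReductionResult:
    """Keep observations by accreting pairs of points sorted by distance.

    ``high`` consumes pairs from the shortest distance up, keeping both
    members of each pair, until the target count is reached (the last
    pair may contribute a single point) — yielding a high-density subset.
    ``low`` consumes pairs from the longest distance down.  The distance
    of the last pair consumed is reported as the threshold ``D``.  Pair
    distances are computed once on the full space (single pass), not
    recomputed after each removal.
    """
    if direction not in _DIRECTIONS["density"]:
        raise ValueError(f"density direction must be high or low, got {direction!r}")
    x = _as_matrix(space)
    n = x.shape[0]
    if n < 4:
        raise ValueError("density reduction needs at least 4 observations")
    k = _n_keep(n, fraction)
    ii, jj = np.triu_indices(n, 1)
    w = pdist(x)
    order = np.lexsort((jj, ii, w))  # ties by pair index
    if direction == "low":
        order = order[::-1]
    kept: list[int] = []
    in_set = np.zeros(n, dtype=bool)
    threshold = float("nan")
    for e in order:
        for p in (int(ii[e]), int(jj[e])):
            if not in_set[p]:
                in_set[p] = True
                kept.append(p)
                threshold = float(w[e])
                if len(kept) == k:
                    return ReductionResult(in_set, "density", direction,
                                           fraction, threshold=threshold)
    raise RuntimeError("pair accretion exhausted before reaching the target count")


def reduce_position(space, fraction: float = 0.5, direction: str = "positive",
                    center: str = "origin") -> ReductionResult:
    """Keep observations by distance from the furthest point from the centre.

    The anchor is the observation with maximal distance from the centre
    (ties broken by lowest row index).  ``positive`` keeps the points
    closest to the anchor (a cluster displaced toward one side of the
    space); ``negative`` keeps the points furthest from it.
    """
    if direction not in _DIRECTIONS["position"]:
        raise ValueError(f"position direction must be positive or negative, got {direction!r}")
    x = _as_matrix(space)
    k = _n_keep(x.shape[0], fraction)
    ref = x.mean(axis=0) if center == "centroid" else np.zeros(x.shape[1])
    far = int(np.argmax(np.linalg.norm(x - ref, axis=1)))
    dist = np.linalg.norm(x - x[far], axis=1)
    mask, rho = _keep_by_rank(dist, k, keep_smallest=(direction == "positive"))
    return ReductionResult(mask, "position", direction, fraction, threshold=rho)


def reduce_space(space, algorithm: str, direction: str | None = None,
                 fraction: float = 0.5, seed: int = 0, **kwargs) -> ReductionResult:
    """Dispatch to one of the four reduction algorithms by name."""
    if algorithm not in _DIRECTIONS:
        raise ValueError(f"unknown algorithm {algorithm!r}; known: {list(_DIRECTIONS)}")
    if direction is None:
        direction = _DIRECTIONS[algorithm][0]
    if direction not in _DIRECTIONS[algorithm]:
        raise ValueError(
            f"direction {direction!r} invalid for {algorithm} "
            f"(allowed: {_DIRECTIONS[algorithm]})"
        )
    if algorithm == "random":
        return reduce_random(space, fraction, seed=seed)
    if algorithm == "size":
        return reduce_size(space, fraction, direction, **kwargs)
    if algorithm == "density":
        return reduce_density(space, fraction, direction)
    return reduce_position(space, fraction, direction, **kwargs)
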