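"""Simulation of multidimensional trait spaces.

A trait space is an ``n x d`` matrix whose rows are observations (taxa,
specimens, field sites) and whose columns are trait dimensions — a
morphospace or an ecospace.  The simulator draws each column from a
declared marginal distribution, optionally applies a decreasing
per-dimension variance scheme (emulating the scree of an ordination such
as a PCA or PCoA without actually ordinating anything), and optionally
imposes random inter-dimension correlation (emulating collinear traits).

The built-in suite (:func:`builtin_space_suite`) covers 13 canonical
space types combining 3–150 dimensions, uniform/normal/lognormal
marginals, equal or decreasing variance, and random correlation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Distribution",
    "SpaceSpec",
    "TraitSpace",
    "simulate_space",
    "variance_scaling_vector",
    "make_correlation_matrix",
    "builtin_space_suite",
    "BUILTIN_SPECS",
    "derive_seed",
]

_VARIANCE_SCHEMES = ("equal", "multiplicative", "additive")

# Default marginal parameters used by the "random-mix" family.
_MIX_FAMILIES = (
    ("normal", (0.0, 1.0)),
    ("uniform", (-0.5, 0.5)),
    ("lognormal", (0.0, 1.0)),
)


@dataclass(frozen=True)
class Distribution:
    """Marginal distribution descriptor for one trait dimension.

    Families: ``uniform(min, max)``, ``normal(mean, sd)``,
    ``lognormal(meanlog, sdlog)`` and ``random-mix`` (the family itself is
    drawn per dimension at simulation time).  Lognormal columns are
    centred by subtracting the theoretical median ``exp(meanlog)`` so that
    simulated spaces stay roughly origin-centred, which the position
    measures rely on.
    """

    family: str
    params: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        fam = self.family
        p = self.params
        if fam == "uniform":
            if len(p) != 2 or not (p[0] < p[1]):
                raise ValueError(f"uniform requires min < max, got {p}")
        elif fam == "normal":
            if len(p) != 2 or p[1] <= 0:
                raise ValueError(f"normal requires sd > 0, got {p}")
        elif fam == "lognormal":
            if len(p) != 2 or p[1] <= 0:
                raise ValueError(f"lognormal requires sdlog > 0, got {p}")
        elif fam == "random-mix":
            if p:
                raise ValueError("random-mix takes no parameters")
        else:
            raise ValueError(f"unknown distribution family {fam!r}")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` values; ``random-mix`` first draws a concrete family."""
        fam, p = self.family, self.params
        if fam == "random-mix":
            fam, p = _MIX_FAMILIES[rng.integers(len(_MIX_FAMILIES))]
        if fam == "uniform":
            return rng.uniform(p[0], p[1], size=n)
        if fam == "normal":
            return rng.normal(p[0], p[1], size=n)
        # lognormal, centred on its theoretical median exp(meanlog)
        return rng.lognormal(p[0], p[1], size=n) - np.exp(p[0])

    @classmethod
    def parse(cls, text: str) -> "Distribution":
        """Parse ``'normal(0, 1)'``-style descriptors (used by the CLI)."""
        text = text.strip()
        if text == "random-mix":
            return cls("random-mix")
        m = re.fullmatch(r"(\w+)\(([^)]*)\)", text)
        if m is None:
            raise ValueError(f"cannot parse distribution {text!r}")
        params = tuple(float(x) for x in m.group(2).split(",")) if m.group(2).strip() else ()
        return cls(m.group(1), params)


def _as_distribution(d) -> Distribution:
    if isinstance(d, Distribution):
        return d
    if isinstance(d, str):
        return Distribution.parse(d)
    if isinstance(d, (tuple, list)):
        return Distribution(d[0], tuple(d[1:]))
    raise TypeError(f"cannot interpret {d!r} as a distribution")


@dataclass(frozen=True)
class SpaceSpec:
    """Recipe for simulating one trait space.

    Parameters
    ----------
    name : str
        Label carried into results tables.
    n_obs, n_dim : int
        Matrix shape (observations x dimensions).
    dists : sequence of Distribution (or parseable descriptors)
        One per dimension, or a single descriptor recycled to all.
    variance_scheme : {"equal", "multiplicative", "additive"}
        Per-dimension standard-deviation decay; see
        :func:`variance_scaling_vector`.
    correlation : None or (lo, hi)
        If given, random pairwise correlations drawn uniformly in
        ``[lo, hi]`` are imposed between dimensions.
    seed : int
        Seed for all randomness of this space.
    """

    name: str
    n_obs: int
    n_dim: int
    dists: tuple[Distribution, ...] = (Distribution("normal", (0.0, 1.0)),)
    variance_scheme: str = "equal"
    correlation: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_obs < 2:
            raise ValueError("n_obs must be >= 2")
        if self.n_dim < 1:
            raise ValueError("n_dim must be >= 1")
        dists = tuple(_as_distribution(d) for d in (
            self.dists if isinstance(self.dists, (tuple, list)) else [self.dists]
        ))
        if len(dists) not in (1, self.n_dim):
            raise ValueError(
                f"dists must have length 1 or n_dim={self.n_dim}, got {len(dists)}"
            )
        object.__setattr__(self, "dists", dists)
        if self.variance_scheme not in _VARIANCE_SCHEMES:
            raise ValueError(
                f"variance_scheme must be one of {_VARIANCE_SCHEMES}, "
                f"got {self.variance_scheme!r}"
            )
        if self.correlation is not None:
            lo, hi = self.correlation
            if not (0 <= lo <= hi < 1):
                raise ValueError(f"correlation bounds need 0 <= lo <= hi < 1, got {self.correlation}")


@dataclass
class TraitSpace:
    """An ``n x d`` trait-space matrix with row/column labels.

    All entries must be finite; row and column ids must be unique.
    """

    data: np.ndarray
    spec: SpaceSpec | None = None
    row_ids: list[str] = field(default_factory=list)
    col_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 1:
            self.data = self.data[:, None]
        if self.data.ndim != 2:
            raise ValueError("trait-space data must be a 2D matrix")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("trait-space data contains non-finite values")
        n, d = self.data.shape
        if not self.row_ids:
            self.row_ids = [f"obs_{i}" for i in range(n)]
        if not self.col_ids:
            self.col_ids = [f"dim_{j}" for j in range(d)]
        if len(self.row_ids) != n or len(set(self.row_ids)) != n:
            raise ValueError("row_ids must be unique and match the number of rows")
        if len(self.col_ids) != d or len(set(self.col_ids)) != d:
            raise ValueError("col_ids must be unique and match the number of columns")

    @property
    def n_obs(self) -> int:
        return self.data.shape[0]

    @property
    def n_dim(self) -> int:
        return self.data.shape[1]

    @property
    def name(self) -> str:
        return self.spec.name if self.spec is not None else "trait_space"

    def subset(self, keep_mask: np.ndarray) -> "TraitSpace":
        """Row subset keeping labels (used by the space reductions)."""
        keep_mask = np.asarray(keep_mask, dtype=bool)
        if keep_mask.shape != (self.n_obs,):
            raise ValueError("keep_mask length must equal the number of observations")
        rows = [r for r, k in zip(self.row_ids, keep_mask) if k]
        return TraitSpace(self.data[keep_mask], spec=self.spec,
                          row_ids=rows, col_ids=list(self.col_ids))


def variance_scaling_vector(n_dim: int, scheme: str) -> np.ndarray:
    """Per-dimension standard-deviation multipliers.

    ``equal`` gives all ones.  ``multiplicative`` uses the cumulative
    product of ``1/d`` (a geometric decay, PCA-like scree);
    ``additive`` the cumulative sum of ``1/d`` (a linear decay, PCoA-like
    scree).  Both decreasing schemes are renormalised so the first
    dimension has multiplier 1 — only the relative decay matters to the
    occupancy measures.
    """
    if n_dim < 1:
        raise ValueError("n_dim must be >= 1")
    if scheme == "equal":
        return np.ones(n_dim)
    if scheme == "multiplicative":
        v = np.cumprod(np.full(n_dim, 1.0 / n_dim))
    elif scheme == "additive":
        v = np.sort(np.cumsum(np.full(n_dim, 1.0 / n_dim)))[::-1]
    else:
        raise ValueError(f"unknown variance scheme {scheme!r}")
    return v / v[0]


def make_correlation_matrix(
    n_dim: int,
    lo: float,
    hi: float,
    seed: int | np.random.Generator = 0,
    floor: float = 1e-8,
    max_iter: int = 200,
) -> np.ndarray:
    """Random correlation matrix with off-diagonals drawn in ``[lo, hi]``.

    Uniform pairwise correlations generically yield an indefinite matrix,
    so the draw is projected to the nearest positive-definite correlation
    matrix by alternating eigenvalue clipping (at ``floor``) and
    unit-diagonal rescaling.

    Raises
    ------
    RuntimeError
        If the projection fails to reach positive definiteness within
        ``max_iter`` sweeps.
    """
    if not (0 <= lo <= hi < 1):
        raise ValueError(f"require 0 <= lo <= hi < 1, got lo={lo}, hi={hi}")
    if n_dim < 1:
        raise ValueError("n_dim must be >= 1")
    if n_dim == 1:
        return np.ones((1, 1))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    c = np.eye(n_dim)
    iu = np.triu_indices(n_dim, 1)
    off = rng.uniform(lo, hi, size=len(iu[0]))
    c[iu] = off
    c.T[iu] = off
    for _ in range(max_iter):
        w, v = np.linalg.eigh(c)
        if w[0] > floor / 2:
            return c
        w = np.clip(w, floor, None)
        c = (v * w) @ v.T
        # rescale to unit diagonal, keep exact symmetry
        s = np.sqrt(np.diag(c))
        c = c / np.outer(s, s)
        c = (c + c.T) / 2
        np.fill_diagonal(c, 1.0)
    raise RuntimeError(
        f"positive-definite projection did not converge for d={n_dim} "
        f"(min eigenvalue {np.linalg.eigvalsh(c)[0]:.3e})"
    )


def simulate_space(spec: SpaceSpec) -> TraitSpace:
    """Simulate a trait space from a :class:`SpaceSpec`.

    Columns are drawn i.i.d. from their marginal descriptors, scaled by
    the variance scheme, then mixed by the Cholesky factor of the random
    correlation matrix (if any).  Imposing correlation after non-normal
    marginal generation distorts those marginals slightly; this simple
    linear construction is deliberate and documented.
    """
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n_obs, spec.n_dim
    dists = spec.dists if len(spec.dists) == d else spec.dists * d
    x = np.column_stack([dists[j].sample(n, rng) for j in range(d)])
    x *= variance_scaling_vector(d, spec.variance_scheme)
    if spec.correlation is not None and d > 1:
        lo, hi = spec.correlation
        corr = make_correlation_matrix(d, lo, hi, seed=rng)
        x = x @ np.linalg.cholesky(corr).T
    return TraitSpace(x, spec=spec)


def derive_seed(base_seed: int, *key: int) -> int:
    """Deterministic per-task seed derived from a base seed and an index key.

    Uses :class:`numpy.random.SeedSequence` spawn keys, so distinct keys
    give statistically independent streams and the mapping is stable
    across platforms.
    """
    ss = np.random.SeedSequence(base_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0])


def _suite_specs(n_obs: int = 200) -> list[SpaceSpec]:
    uni = Distribution("uniform", (-0.5, 0.5))
    norm = Distribution("normal", (0.0, 1.0))
    mix = Distribution("random-mix")
    corr = (0.1, 0.9)
    return [
        SpaceSpec("3D uniform", n_obs, 3, (uni,)),
        SpaceSpec("15D uniform", n_obs, 15, (uni,)),
        SpaceSpec("50D uniform", n_obs, 50, (uni,)),
        SpaceSpec("150D uniform", n_obs, 150, (uni,)),
        SpaceSpec("50D uniform correlated", n_obs, 50, (uni,), correlation=corr),
        SpaceSpec("3D normal", n_obs, 3, (norm,)),
        SpaceSpec("15D normal", n_obs, 15, (norm,)),
        SpaceSpec("50D normal", n_obs, 50, (norm,)),
        SpaceSpec("150D normal", n_obs, 150, (norm,)),
        SpaceSpec("50D normal correlated", n_obs, 50, (norm,), correlation=corr),
        SpaceSpec("50D with random distributions", n_obs, 50, (mix,)),
        SpaceSpec("50D PCA-like", n_obs, 50, (norm,), variance_scheme="multiplicative"),
        SpaceSpec("50D PCO-like", n_obs, 50, (norm,), variance_scheme="additive"),
    ]


#: The 13 canonical space recipes (200 observations each).
BUILTIN_SPECS: tuple[SpaceSpec, ...] = tuple(_suite_specs())


def builtin_space_suite(
    n_replicates: int = 20,
    base_seed: int = 42,
    n_obs: int = 200,
) -> list[TraitSpace]:
    """Simulate the 13-type suite, ``n_replicates`` times each.

    Returns ``13 * n_replicates`` spaces in deterministic order
    (space-type major, replicate minor); per-space seeds are derived from
    ``base_seed`` via :func:`derive_seed`.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    spaces = []
    for i, spec in enumerate(_suite_specs(n_obs)):
        for rep in range(n_replicates):
            s = replace(spec, seed=derive_seed(base_seed, i, rep))
            spaces.append(simulate_space(s))
    return spaces
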