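"""End-to-end simulation study of occupancy-measure behaviour.

:func:`run_study` orchestrates the whole experiment:

1. simulate the 13-type trait-space suite, ``n_replicates`` replicates
   each (260 spaces at the default 20);
2. apply the seven reduction scenarios to every space (1 random +
   size/density/position in both directions), each removing
   ``1 - fraction`` of the observations;
3. compute every occupancy measure on each full and reduced space;
4. scale the reduced-space values against the unreduced baseline of the
   same space type, per measure and scenario;
5. summarise: Bhattacharyya overlap of each non-random scenario against
   the random null, the measure-by-measure Pearson correlation matrix,
   and one-way ANOVAs for the effect of marginal distribution (among the
   50-dimension space types) and of dimensionality (across the uniform
   and normal equal-variance series).

Everything is reproducible from ``base_seed``.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .simulator import (SpaceSpec, TraitSpace, simulate_space, derive_seed,
                        _suite_specs)
from .measures import measure_registry, apply_measures, BUILTIN_MEASURES
from .reduction import reduce_space, SCENARIOS
from .stats import (scale_measure_values, bhattacharyya_coefficient,
                    pairwise_measure_correlations, one_way_anova_f)

__all__ = ["StudyConfig", "StudyReport", "run_study", "correlation_report",
           "anova_report", "overlap_report"]

#: Scenario labels: the full (unreduced) space plus the seven reductions.
FULL = "full"
SCENARIO_LABELS = tuple(
    alg if alg == "random" else f"{alg}_{direction}" for alg, direction in SCENARIOS
)

# 50-dimension space types used for the distribution-effect ANOVA.
_DISTRIBUTION_TYPES = (
    "50D uniform", "50D normal", "50D uniform correlated", "50D normal correlated",
    "50D with random distributions", "50D PCA-like", "50D PCO-like",
)
# Equal-variance uncorrelated series used for the dimensionality-effect ANOVA.
_DIMENSION_TYPES = {
    "3D uniform": 3, "15D uniform": 15, "50D uniform": 50, "150D uniform": 150,
    "3D normal": 3, "15D normal": 15, "50D normal": 50, "150D normal": 150,
}


@dataclass
class StudyConfig:
    """Configuration of the simulation study."""

    n_replicates: int = 20
    fraction: float = 0.5
    measures: tuple[str, ...] = BUILTIN_MEASURES
    n_bins: int | None = None  # Bhattacharyya bin count (None = sqrt rule)
    base_seed: int = 42
    n_obs: int = 200
    correlate_on: str = "full_per_type"  # "full_per_type", "scaled" or "raw_full"
    output_dir: str | None = None

    def __post_init__(self) -> None:
        unknown = [m for m in self.measures if m not in measure_registry]
        if unknown:
            raise ValueError(f"unknown measures in config: {unknown}")
        if self.correlate_on not in ("full_per_type", "scaled", "raw_full"):
            raise ValueError(
                "correlate_on must be 'full_per_type', 'scaled' or 'raw_full'")


@dataclass
class StudyReport:
    """All tables produced by :func:`run_study`."""

    config: StudyConfig
    raw: pd.DataFrame        # space_type, replicate, scenario, measure, value...
    scaled: pd.DataFrame     # per-replicate scaled change scores
    overlaps: pd.DataFrame   # BC of each scenario vs the random null, per measure
    correlations: pd.DataFrame
    anova: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    def write(self, output_dir) -> None:
        """Write all tables plus a machine-readable manifest."""
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.raw.to_csv(out / "raw_measures.csv", index=False)
        self.scaled.to_csv(out / "scaled_changes.csv", index=False)
        self.overlaps.to_csv(out / "scenario_overlaps.csv")
        self.correlations.to_csv(out / "measure_correlations.csv")
        self.anova.to_csv(out / "anova.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2) + "\n")


def _measure_rows(space, measures, space_type, replicate, scenario):
    rows = []
    for mv in apply_measures(space, list(measures)):
        rows.append({
            "space_type": space_type, "replicate": replicate, "scenario": scenario,
            "measure": mv.name, "category": mv.category,
            "value": mv.value if mv.valid else math.nan,
            "valid": mv.valid,
        })
    return rows


def run_study(config: StudyConfig | None = None, **kwargs) -> StudyReport:
    """Run the full simulation study; see the module docstring for the steps."""
    if config is None:
        config = StudyConfig(**kwargs)
    elif kwargs:
        config = replace(config, **kwargs)

    rows = []
    specs = _suite_specs(config.n_obs)
    for i, spec in enumerate(specs):
        for rep in range(config.n_replicates):
            space = simulate_space(replace(spec, seed=derive_seed(config.base_seed, i, rep)))
            rows.extend(_measure_rows(space, config.measures, spec.name, rep, FULL))
            for s, (alg, direction) in enumerate(SCENARIOS):
                res = reduce_space(space, alg, direction, fraction=config.fraction,
                                   seed=derive_seed(config.base_seed, i, rep, s))
                label = alg if alg == "random" else f"{alg}_{direction}"
                rows.extend(_measure_rows(res.apply(space), config.measures,
                                          spec.name, rep, label))
    raw = pd.DataFrame(rows)

    scaled = _scale_study(raw, config)
    overlaps = overlap_report(scaled, n_bins=config.n_bins)
    correlations = _correlations(raw, scaled, config.correlate_on)
    anova = anova_report(scaled)

    manifest = {
        "package": "traitspaces",
        "version": __version__,
        "numpy": np.__version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "n_spaces": int(config.n_replicates * len(specs)),
        "scenarios": list(SCENARIO_LABELS),
    }
    report = StudyReport(config, raw, scaled, overlaps, correlations, anova, manifest)
    if config.output_dir:
        report.write(config.output_dir)
    return report


def _scale_study(raw: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Per-replicate scaled change scores, normalised per space type.

    The normaliser for a (space type, measure) pair is the maximum
    absolute unreduced value across that type's replicates, so the same
    baseline scale applies to every scenario of that type.
    """
    out = []
    full = (raw[raw.scenario == FULL]
            .set_index(["space_type", "measure", "replicate"]).value.sort_index())
    for (space_type, measure), grp in raw[raw.scenario != FULL].groupby(
            ["space_type", "measure"], sort=False):
        base = full.loc[space_type, measure]
        for scenario, sub in grp.groupby("scenario", sort=False):
            sub = sub.set_index("replicate")
            reps = sub.index.to_numpy()
            f = base.reindex(reps).to_numpy()
            r = sub.value.to_numpy()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sv = scale_measure_values(f, r)
            ok = np.isfinite(f) & np.isfinite(r)
            for rep, rf, rr, sc in zip(reps[ok], f[ok], r[ok], sv.scaled):
                out.append({
                    "space_type": space_type, "measure": measure,
                    "scenario": scenario, "replicate": int(rep),
                    "raw_full": rf, "raw_reduced": rr, "scaled": sc,
                })
    return pd.DataFrame(out)


def overlap_report(scaled: pd.DataFrame, n_bins: int | None = None) -> pd.DataFrame:
    """Bhattacharyya overlap of each scenario's scaled values vs the random null.

    Values are pooled across all space types and replicates, per measure.
    The random scenario against itself is 1 by construction and is kept
    as a sanity row.
    """
    measures = scaled.measure.unique()
    scenarios = [s for s in SCENARIO_LABELS]
    table = pd.DataFrame(index=pd.Index(measures, name="measure"),
                         columns=scenarios, dtype=float)
    for measure in measures:
        sub = scaled[scaled.measure == measure]
        null = sub[sub.scenario == "random"].scaled.to_numpy()
        null = null[np.isfinite(null)]
        for scenario in scenarios:
            vals = sub[sub.scenario == scenario].scaled.to_numpy()
            vals = vals[np.isfinite(vals)]
            if null.size == 0 or vals.size == 0:
                continue
            table.loc[measure, scenario] = bhattacharyya_coefficient(
                vals, null, n_bins=n_bins).bc
    return table


def _scale_within_type(col: pd.Series) -> pd.Series:
    """Standardise one measure's values across the replicates of one space type.

    Values are first divided by their maximum absolute value so that
    measures spanning extreme magnitudes (ellipsoid volumes underflow
    toward the float limit in high dimensions) remain computable, then
    centred and reduced.  Constant or all-invalid columns become NaN.
    """
    c = col / max(col.abs().max(), np.finfo(float).tiny)
    sd = c.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        return col * np.nan
    return (c - c.mean()) / sd


def _correlations(raw: pd.DataFrame, scaled: pd.DataFrame, on: str) -> pd.DataFrame:
    if on == "raw_full":
        wide = raw[raw.scenario == FULL].pivot_table(
            index=["space_type", "replicate"], columns="measure", values="value",
            dropna=False)
    elif on == "full_per_type":
        wide = raw[raw.scenario == FULL].pivot_table(
            index=["space_type", "replicate"], columns="measure", values="value",
            dropna=False)
        wide = wide.groupby(level="space_type").transform(_scale_within_type)
    else:
        wide = scaled.pivot_table(
            index=["space_type", "replicate", "scenario"], columns="measure",
            values="scaled", dropna=False)
    order = [m for m in raw.measure.unique() if m in wide.columns]
    return pairwise_measure_correlations(wide[order])


def correlation_report(study: StudyReport, on: str | None = None) -> pd.DataFrame:
    """Measure-by-measure Pearson correlation matrix from a finished study."""
    if on is None or on == study.config.correlate_on:
        return study.correlations
    return _correlations(study.raw, study.scaled, on)


def anova_report(scaled: pd.DataFrame) -> pd.DataFrame:
    """One-way ANOVAs for distribution and dimensionality effects.

    Per measure, the scaled change scores (pooled over scenarios and
    replicates) are grouped (a) by space type among the seven
    50-dimension types, testing the effect of the marginal distribution
    and variance/correlation structure, and (b) by dimension count across
    the uniform and normal equal-variance series, testing the effect of
    dimensionality.
    """
    rows = []
    for measure, sub in scaled.groupby("measure", sort=False):
        dist = sub[sub.space_type.isin(_DISTRIBUTION_TYPES)]
        dim = sub[sub.space_type.isin(_DIMENSION_TYPES)].copy()
        dim["n_dim"] = dim.space_type.map(_DIMENSION_TYPES)
        for factor, data, key in (("distribution", dist, "space_type"),
                                  ("dimensions", dim, "n_dim")):
            vals = data.scaled.to_numpy()
            grp = data[key].to_numpy()
            ok = np.isfinite(vals)
            try:
                res = one_way_anova_f(vals[ok], grp[ok])
                rows.append({"measure": measure, "factor": factor, "f": res.f,
                             "p": res.p, "df_between": res.df_between,
                             "df_within": res.df_within})
            except ValueError:
                rows.append({"measure": measure, "factor": factor, "f": math.nan,
                             "p": math.nan, "df_between": math.nan,
                             "df_within": math.nan})
    return pd.DataFrame(rows)
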