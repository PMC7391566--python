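"""Reading and writing trait spaces, group files and result tables.

Trait spaces are exchanged as delimited text: a header row of dimension
labels, first column of row ids.  Floats are written with full precision
(Python repr) so a write/read cycle is bit-exact.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simulator import TraitSpace

__all__ = [
    "read_trait_space",
    "write_trait_space",
    "read_groups",
    "write_groups",
    "write_reduction",
]


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def write_trait_space(space: TraitSpace, path, sep: str | None = None) -> None:
    """Write a trait space as delimited text (CSV by default, TSV by suffix)."""
    path = Path(path)
    df = pd.DataFrame(space.data, index=space.row_ids, columns=space.col_ids)
    df.to_csv(path, sep=_sep_for(path, sep), index_label="id")


def read_trait_space(path, sep: str | None = None) -> TraitSpace:
    """Read a delimited trait-space matrix (first column = row ids)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep), index_col=0,
                     float_precision="round_trip")
    if df.shape[1] < 1:
        raise ValueError(f"{path}: no trait dimensions found")
    data = df.to_numpy(dtype=float)
    return TraitSpace(data, row_ids=[str(i) for i in df.index],
                      col_ids=[str(c) for c in df.columns])


def read_groups(path, sep: str | None = None) -> dict[str, str]:
    """Read a two-column (id, group) delimited file into a mapping."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep))
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (id, group)")
    ids = df.iloc[:, 0].astype(str)
    if ids.duplicated().any():
        raise ValueError(f"{path}: duplicate row ids in group file")
    return dict(zip(ids, df.iloc[:, 1].astype(str)))


def write_groups(groups: dict[str, str], path, sep: str | None = None) -> None:
    path = Path(path)
    pd.DataFrame({"id": list(groups), "group": list(groups.values())}).to_csv(
        path, sep=_sep_for(path, sep), index=False)


def write_reduction(result, space: TraitSpace, path, sep: str | None = None) -> None:
    """Serialise a reduction: metadata header lines, then (row_id, kept)."""
    path = Path(path)
    s = _sep_for(path, sep)
    lines = [
        f"# algorithm{s}{result.algorithm}",
        f"# direction{s}{result.direction}",
        f"# fraction{s}{result.target_fraction!r}",
        f"# threshold{s}{'' if result.threshold is None else repr(result.threshold)}",
        f"# seed{s}{'' if result.seed is None else result.seed}",
        f"id{s}kept",
    ]
    for rid, kept in zip(space.row_ids, result.keep_mask):
        lines.append(f"{rid}{s}{int(kept)}")
    path.write_text("\n".join(lines) + "\n")
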