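"""Traced-fibre centreline representation and the fibre-table CSV dialect.

A :class:`FibrePolyline` is one traced fibre bundle: an ordered chain of 3D
vertices in physical µm, labelled by lamella (1 = outermost, increasing
inward) and a fibre number within the dataset.  The on-disk form is a flat
CSV with header ``lamella,fibre,vertex,x,y,z`` — the same dialect is used
for phantom ground truth and for ingesting externally traced centrelines,
so the tracing stage can be bypassed entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["FibrePolyline", "read_fibre_table", "write_fibre_table", "polylines_to_table", "table_to_polylines"]

FIBRE_TABLE_COLUMNS = ["lamella", "fibre", "vertex", "x", "y", "z"]


@dataclass
class FibrePolyline:
    """One fibre centreline as an ordered vertex chain (µm)."""

    lamella: int
    fibre: int
    vertices: np.ndarray
    #: optional per-vertex ground truth attached by the phantom generator
    true_tangent: np.ndarray | None = field(default=None, repr=False)
    true_curvature: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (N, 3) array")
        if len(self.vertices) < 2:
            raise ValueError("a polyline needs at least 2 vertices")
        steps = np.linalg.norm(np.diff(self.vertices, axis=0), axis=1)
        if np.any(steps <= 0):
            raise ValueError("consecutive vertices must be distinct")

    @property
    def length(self) -> float:
        """Total chord length in µm."""
        return float(np.linalg.norm(np.diff(self.vertices, axis=0), axis=1).sum())

    def arc_lengths(self) -> np.ndarray:
        """Cumulative chord length at each vertex, starting at 0."""
        steps = np.linalg.norm(np.diff(self.vertices, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(steps)])


def polylines_to_table(fibres: list[FibrePolyline]) -> pd.DataFrame:
    rows = []
    for fb in fibres:
        n = len(fb.vertices)
        rows.append(
            pd.DataFrame(
                {
                    "lamella": np.full(n, fb.lamella, dtype=int),
                    "fibre": np.full(n, fb.fibre, dtype=int),
                    "vertex": np.arange(n, dtype=int),
                    "x": fb.vertices[:, 0],
                    "y": fb.vertices[:, 1],
                    "z": fb.vertices[:, 2],
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=FIBRE_TABLE_COLUMNS)
    return pd.concat(rows, ignore_index=True)


def table_to_polylines(table: pd.DataFrame) -> list[FibrePolyline]:
    out = []
    for (lam, fib), grp in table.groupby(["lamella", "fibre"], sort=True):
        grp = grp.sort_values("vertex")
        out.append(FibrePolyline(int(lam), int(fib), grp[["x", "y", "z"]].to_numpy()))
    return out


def write_fibre_table(fibres: list[FibrePolyline] | pd.DataFrame, path: str | Path) -> None:
    table = fibres if isinstance(fibres, pd.DataFrame) else polylines_to_table(fibres)
    table.to_csv(path, index=False, columns=FIBRE_TABLE_COLUMNS)


def read_fibre_table(path: str | Path) -> list[FibrePolyline]:
    table = pd.read_csv(path)
    missing = set(FIBRE_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"fibre table {path} is missing columns {sorted(missing)}")
    return table_to_polylines(table)
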