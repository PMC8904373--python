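"""Hierarchical evenly-spaced point-cloud seeding along traced fibres.

Each traced fibre is resampled at fixed arc-length intervals (default 8 µm,
the spacing used for all per-point metrics), producing the labelled point
cloud ``(l, f, p, n, x, y, z, s)`` that seeds sub-volume correlation and
anchors every downstream quantity:

- ``l`` lamella number (1 = outermost), ``f`` fibre number, ``p`` point
  index along the fibre from its trace start,
- ``n`` a unique global point number assigned in ``(l, f, p)`` order,
- ``s`` the cumulative chord arc length from the fibre start in µm — the
  curve parameter of the space-curve fits.

Arc length is measured on the raw polyline (cumulative chord length), and
only exact multiples of the spacing are kept, so the s-grid is uniform for
polynomial fitting.  Fibres yielding fewer than 4 points — the minimum a
cubic fit needs — are excluded and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .fibres import FibrePolyline

__all__ = ["FibrePointCloud", "seed_points", "read_point_cloud", "write_point_cloud"]

logger = logging.getLogger(__name__)

MIN_POINTS_PER_FIBRE = 4

CLOUD_COLUMNS = ["l", "f", "p", "n", "x", "y", "z", "s"]


@dataclass
class FibrePointCloud:
    """Evenly spaced labelled points along all fibres (positions in µm)."""

    points: pd.DataFrame
    spacing: float
    voxel_size: float = 1.625

    def __post_init__(self) -> None:
        missing = set(CLOUD_COLUMNS) - set(self.points.columns)
        if missing:
            raise ValueError(f"point cloud is missing columns {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def n_fibres(self) -> int:
        return self.points.groupby(["l", "f"]).ngroups

    def positions_vox(self) -> np.ndarray:
        """(N, 3) point positions in voxel units."""
        return self.points[["x", "y", "z"]].to_numpy() / self.voxel_size

    def fibre_groups(self):
        """Iterate (``(l, f)``, sub-table) per fibre in label order."""
        return self.points.groupby(["l", "f"], sort=True)


def _resample_polyline(vertices: np.ndarray, spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """Positions at arc lengths 0, spacing, 2·spacing, ... along the chain."""
    steps = np.linalg.norm(np.diff(vertices, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    total = cum[-1]
    n_pts = int(np.floor(total / spacing + 1e-9)) + 1
    s = np.arange(n_pts) * spacing
    pos = np.empty((n_pts, 3))
    for ax in range(3):
        pos[:, ax] = np.interp(s, cum, vertices[:, ax])
    return pos, s


def seed_points(fibres: list[FibrePolyline], spacing: float = 8.0, voxel_size: float = 1.625) -> FibrePointCloud:
    """Seed evenly spaced points along every fibre.

    Points sit at exact arc-length multiples of ``spacing`` measured by
    cumulative chord length, linearly interpolated between polyline
    vertices; the trailing remainder shorter than one spacing is dropped.
    Fibres with fewer than 4 points are excluded with a logged reason.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    frames = []
    n_excluded = 0
    for fb in fibres:
        pos, s = _resample_polyline(fb.vertices, spacing)
        if len(pos) < MIN_POINTS_PER_FIBRE:
            n_excluded += 1
            logger.info(
                "excluding fibre (l=%d, f=%d): %d point(s) at spacing %g µm (< %d needed for cubic fitting)",
                fb.lamella, fb.fibre, len(pos), spacing, MIN_POINTS_PER_FIBRE,
            )
            continue
        frames.append(
            pd.DataFrame(
                {
                    "l": np.full(len(pos), fb.lamella, dtype=int),
                    "f": np.full(len(pos), fb.fibre, dtype=int),
                    "p": np.arange(len(pos), dtype=int),
                    "x": pos[:, 0],
                    "y": pos[:, 1],
                    "z": pos[:, 2],
                    "s": s,
                }
            )
        )
    if n_excluded:
        logger.info("excluded %d fibre(s) with < %d points", n_excluded, MIN_POINTS_PER_FIBRE)
    if not frames:
        table = pd.DataFrame(columns=CLOUD_COLUMNS)
        return FibrePointCloud(table, spacing, voxel_size)
    table = pd.concat(frames, ignore_index=True)
    table = table.sort_values(["l", "f", "p"], kind="stable").reset_index(drop=True)
    table["n"] = np.arange(len(table), dtype=int)
    return FibrePointCloud(table[CLOUD_COLUMNS], spacing, voxel_size)


def write_point_cloud(cloud: FibrePointCloud, path: str | Path) -> None:
    table = cloud.points.copy()
    for ax in "xyz":
        table[f"{ax}_vox"] = table[ax] / cloud.voxel_size
    table.attrs["spacing"] = cloud.spacing
    header = f"# spacing_um={cloud.spacing} voxel_size_um={cloud.voxel_size}\n"
    with open(path, "w") as fh:
        fh.write(header)
        table.to_csv(fh, index=False)


def read_point_cloud(path: str | Path) -> FibrePointCloud:
    with open(path) as fh:
        first = fh.readline()
        meta = {}
        if first.startswith("#"):
            meta = dict(kv.split("=") for kv in first[1:].split())
            table = pd.read_csv(fh)
        else:
            fh.seek(0)
            table = pd.read_csv(fh)
    return FibrePointCloud(
        table[CLOUD_COLUMNS],
        spacing=float(meta.get("spacing_um", 8.0)),
        voxel_size=float(meta.get("voxel_size_um", 1.625)),
    )
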