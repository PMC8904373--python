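"""Shared fixtures: small phantoms and clouds generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fibredvc.phantom import PhantomConfig, generate_volume
from fibredvc.seeding import FibrePointCloud, seed_points


@pytest.fixture(scope="session")
def small_phantom():
    """96³ three-lamella phantom with moderate noise; shared across tests."""
    cfg = PhantomConfig(grid_shape=(96, 96, 96), n_lamellae=3, noise_sd=1500.0, depth_margin=10, rng_seed=5)
    vol, truth = generate_volume(cfg)
    return cfg, vol, truth


@pytest.fixture(scope="session")
def small_cloud(small_phantom):
    """Interior-point sub-cloud of ~30 fibres from the small phantom."""
    cfg, vol, truth = small_phantom
    cloud = seed_points(truth.polylines, spacing=8.0, voxel_size=cfg.voxel_size)
    return subsample_interior(cloud, vol.shape, n_fibres=30, margin_vox=18, seed=0)


def subsample_interior(
    cloud: FibrePointCloud,
    shape,
    n_fibres: int,
    margin_vox: float,
    seed: int = 0,
) -> FibrePointCloud:
    """Pick n_fibres at random, keep only points at least margin_vox from faces."""
    rng = np.random.default_rng(seed)
    keys = cloud.points[["l", "f"]].drop_duplicates().reset_index(drop=True)
    pick = keys.iloc[rng.choice(len(keys), size=min(n_fibres, len(keys)), replace=False)]
    sub = cloud.points.merge(pick, on=["l", "f"])
    vox = sub[["x", "y", "z"]].to_numpy() / cloud.voxel_size
    ok = np.all((vox >= margin_vox) & (vox <= np.array(shape) - 1 - margin_vox), axis=1)
    sub = sub[ok].sort_values(["l", "f", "p"]).reset_index(drop=True)
    # drop fibres reduced below the cubic-fit minimum by the interior crop
    counts = sub.groupby(["l", "f"])["p"].transform("size")
    sub = sub[counts >= 4].reset_index(drop=True)
    sub["n"] = np.arange(len(sub))
    return FibrePointCloud(sub, cloud.spacing, cloud.voxel_size)
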