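"""Validation studies: tracking accuracy and strain uncertainty on phantoms.

These drivers reproduce the two methodological checks used to qualify the
tracking pipeline:

- :func:`tracking_accuracy_study` — deform the phantom by a known smooth
  sub-voxel field (tricubic resampling plus fresh image noise), correlate a
  set of randomly seeded interior points, and report the mean Euclidean
  error between recovered and ground-truth displacements (voxels);
- :func:`strain_uncertainty_study_at_worst_case` — self-correlate the
  phantom against noise-added copies of itself (true strain identically
  zero) and push the displacements through the full space-curve /
  displacement-gradient pipeline, reporting the standard deviation of the
  along-fibre Lagrange strain at each noise level up to the worst case
  (the grey-value sd measured in the phantom's structure-free background
  region, added on top of the already-noisy reference).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .dvc import DvcParams, correlate_points, strain_uncertainty_study
from .phantom import (
    PhantomConfig,
    RippleTranslation,
    add_noise,
    deform_volume,
    generate_volume,
    worst_case_noise_sd,
)
from .seeding import FibrePointCloud, seed_points

__all__ = ["tracking_accuracy_study", "strain_uncertainty_study_at_worst_case", "interior_fibre_cloud"]

logger = logging.getLogger(__name__)

#: margin (voxels) keeping a 30-voxel sphere plus interpolation stencil inside
SPHERE_MARGIN = 18.0


def tracking_accuracy_study(
    config: PhantomConfig | None = None,
    n_points: int = 2000,
    params: DvcParams | None = None,
    translation=(0.3, -0.2, 0.5),
    ripple_amplitude: float = 0.15,
    ripple_wavelength: float = 120.0,
    rng_seed: int = 0,
) -> dict:
    """Mean 3D displacement-tracking error at randomly seeded points.

    The phantom (default configuration, seeded) is deformed by a rigid
    sub-voxel translation plus a low-amplitude smooth sinusoidal
    perturbation, resampled tricubically, and given a fresh draw of the
    configured Gaussian image noise; ``n_points`` uniformly random interior
    points are then tracked with the given DVC parameters.
    """
    config = config or PhantomConfig(rng_seed=rng_seed)
    params = params or DvcParams(rng_seed=rng_seed + 1)
    rng = np.random.default_rng(rng_seed + 2)
    vol, truth = generate_volume(config)
    field = RippleTranslation(
        translation, vol.shape, amplitude=ripple_amplitude, wavelength=ripple_wavelength
    )
    dfm = deform_volume(vol, field)
    if config.noise_sd > 0:
        dfm = add_noise(dfm, config.noise_sd, rng)
    lo = SPHERE_MARGIN + float(np.max(np.abs(field.displacement(np.zeros((1, 3)))))) + 1.0
    pts = rng.uniform(lo, np.asarray(vol.shape) - 1 - lo, size=(n_points, 3))
    rec = correlate_points(vol, dfm, pts, params)
    conv = rec["converged"].to_numpy()
    true_u = field.displacement(pts)
    err = np.linalg.norm(rec[["u", "v", "w"]].to_numpy() - true_u, axis=1)
    result = {
        "mean_error_vox": float(err[conv].mean()),
        "median_error_vox": float(np.median(err[conv])),
        "p95_error_vox": float(np.percentile(err[conv], 95)),
        "frac_converged": float(conv.mean()),
        "n_points": int(n_points),
    }
    logger.info("tracking accuracy: %s", result)
    return result


def interior_fibre_cloud(
    config: PhantomConfig,
    truth,
    shape,
    spacing: float = 8.0,
    max_fibres: int = 0,
    margin_vox: float = SPHERE_MARGIN,
) -> FibrePointCloud:
    """Seed the ground-truth fibres and keep sphere-safe interior points.

    Fibres are optionally subsampled (evenly across the table) to keep
    correlation workloads desk-sized; fibres reduced below 4 points by the
    interior crop are dropped.
    """
    cloud = seed_points(truth.polylines, spacing=spacing, voxel_size=config.voxel_size)
    pts = cloud.points
    if max_fibres > 0:
        keys = pts[["l", "f"]].drop_duplicates().reset_index(drop=True)
        if len(keys) > max_fibres:
            pick = keys.iloc[np.linspace(0, len(keys) - 1, max_fibres).round().astype(int)]
            pts = pts.merge(pick, on=["l", "f"])
    vox = pts[["x", "y", "z"]].to_numpy() / config.voxel_size
    ok = np.all((vox >= margin_vox) & (vox <= np.asarray(shape) - 1 - margin_vox), axis=1)
    pts = pts[ok]
    counts = pts.groupby(["l", "f"])["p"].transform("size")
    pts = pts[counts >= 4].sort_values(["l", "f", "p"]).reset_index(drop=True)
    pts["n"] = np.arange(len(pts))
    return FibrePointCloud(pts, spacing, config.voxel_size)


def strain_uncertainty_study_at_worst_case(
    config: PhantomConfig | None = None,
    params: DvcParams | None = None,
    max_fibres: int = 50,
    noise_fractions: tuple[float, ...] = (0.0, 0.25, 0.5, 1.0),
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Strain-uncertainty table over a noise grid up to the worst-case level.

    The worst case is the grey-value noise sd measured in the phantom's
    structure-free background region (the air-noise analogue), added on top
    of the already-noisy reference.  Returns the
    :func:`fibredvc.dvc.strain_uncertainty_study` table with an extra
    ``noise_fraction`` column.
    """
    config = config or PhantomConfig(rng_seed=rng_seed)
    params = params or DvcParams(rng_seed=rng_seed + 1)
    vol, truth = generate_volume(config)
    worst = worst_case_noise_sd(vol, truth)
    cloud = interior_fibre_cloud(config, truth, vol.shape, max_fibres=max_fibres)
    logger.info("worst-case noise sd %.0f grey levels; %d cloud points", worst, len(cloud))
    table = strain_uncertainty_study(
        vol, [f * worst for f in noise_fractions], cloud, params, rng_seed=rng_seed + 3
    )
    table.insert(0, "noise_fraction", list(noise_fractions))
    table.attrs["worst_case_noise_sd"] = worst
    return table
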