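"""End-to-end orchestration: phantom → trace/ingest → seed → DVC → metrics → stats.

A run is described by a single serialisable :class:`RunConfig`; executing it
writes every stage artefact into a run directory together with the resolved
configuration, content hashes of the inputs, and per-stage counts, so a
rerun with the same config reproduces the outputs byte for byte.

One global seed is fanned out to the per-stage seeds by fixed offsets, so
stages stay independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dvc as dvc_mod
from . import metrics as metrics_mod
from . import phantom as phantom_mod
from . import seeding, stats, tracing
from .fibres import read_fibre_table, write_fibre_table
from .seeding import FibrePointCloud
from .volume import read_volume

__all__ = ["RunConfig", "run_all"]

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets fanned out from the global seed
_SEED_PHANTOM = 11
_SEED_DVC = 23
_SEED_NOISE = 37


@dataclass
class RunConfig:
    """Fully serialisable description of one pipeline run."""

    out_dir: str = "run"
    rng_seed: int = 0
    #: phantom geometry (keyword arguments of PhantomConfig), or None when
    #: volumes are supplied
    phantom: dict | None = None
    #: pre-existing load-step volumes (paths), alternative to phantom+load_steps
    volumes: list[str] = field(default_factory=list)
    #: deformation specs per load step relative to the base volume,
    #: e.g. ["stretch:0.98,0.3", "stretch:0.96,0.3"]
    load_steps: list[str] = field(default_factory=list)
    #: externally traced centrelines (fibre-table CSV); bypasses tracing
    fibres_csv: str | None = None
    #: run the cylinder-correlation tracer instead of ground-truth fibres
    trace: bool = False
    cylinder: dict = field(default_factory=dict)
    trace_params: dict = field(default_factory=dict)
    spacing: float = 8.0
    dvc: dict = field(default_factory=dict)
    #: circumferential reference direction for the orientation convention
    c_hat: tuple[float, float, float] = (1.0, 0.0, 0.0)
    region: str = "phantom"
    #: limit the cloud to this many fibres (evenly subsampled); 0 = all
    max_fibres: int = 0
    make_plots: bool = True

    def __post_init__(self) -> None:
        self.c_hat = tuple(float(v) for v in self.c_hat)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        payload = json.loads(json.dumps(dataclasses.asdict(self)))  # tuples -> lists
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _array_hash(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


def _subsample_fibres(cloud: FibrePointCloud, max_fibres: int) -> FibrePointCloud:
    if max_fibres <= 0 or cloud.n_fibres <= max_fibres:
        return cloud
    keys = cloud.points[["l", "f"]].drop_duplicates().reset_index(drop=True)
    pick = keys.iloc[np.linspace(0, len(keys) - 1, max_fibres).round().astype(int)]
    sub = cloud.points.merge(pick, on=["l", "f"]).sort_values(["l", "f", "p"]).reset_index(drop=True)
    sub["n"] = np.arange(len(sub))
    return FibrePointCloud(sub, cloud.spacing, cloud.voxel_size)


def run_all(config: RunConfig) -> Path:
    """Execute all enabled stages in order; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta: dict = {"rng_seed": config.rng_seed, "stages": {}, "input_hashes": {}}

    # --- volumes: phantom generation or ingestion -------------------------
    truth = None
    if config.phantom is not None:
        pc = phantom_mod.PhantomConfig(**{**config.phantom, "rng_seed": config.rng_seed + _SEED_PHANTOM})
        base, truth = phantom_mod.generate_volume(pc)
        vols = [base]
        for spec in config.load_steps:
            fld = phantom_mod.field_from_spec(spec, base.shape)
            vols.append(phantom_mod.deform_volume(base, fld))
        if not config.load_steps:
            logger.info("no load steps configured: single-volume run (reference metrics only)")
        voxel_size = pc.voxel_size
        meta["stages"]["phantom"] = {"config": dataclasses.asdict(pc), "n_true_fibres": int(truth.fibre_table.fibre.nunique())}
        meta["input_hashes"]["base_volume"] = _array_hash(base.data)
    elif config.volumes:
        vols = [read_volume(p) for p in config.volumes]
        voxel_size = vols[0].voxel_size
        for p in config.volumes:
            meta["input_hashes"][p] = _sha256(Path(p))
    else:
        raise ValueError("config must provide either a phantom section or input volumes")
    if len({v.shape for v in vols}) != 1:
        raise ValueError("all load-step volumes must share one shape")

    # --- fibres: trace, ingest, or phantom ground truth -------------------
    if config.fibres_csv:
        fibres = read_fibre_table(config.fibres_csv)
        meta["input_hashes"][config.fibres_csv] = _sha256(Path(config.fibres_csv))
        source = "ingested"
    elif config.trace:
        cyl = tracing.CylinderTemplateParams(**config.cylinder)
        score, dirs = tracing.cylinder_correlate(vols[0], cyl)
        fibres = tracing.trace_fibres(score, dirs, tracing.TraceParams(**config.trace_params), voxel_size=voxel_size)
        if truth is not None:
            bounds = phantom_mod.lamella_boundaries(truth.config)
            fibres = tracing.label_lamellae(fibres, bounds)
        source = "traced"
    elif truth is not None:
        fibres = truth.polylines
        source = "phantom ground truth"
    else:
        raise ValueError("no fibre source: supply fibres_csv or enable tracing")
    write_fibre_table(fibres, out / "fibres.csv")
    meta["stages"]["fibres"] = {"source": source, "count": len(fibres)}
    logger.info("fibres: %d (%s)", len(fibres), source)

    # --- seeding ----------------------------------------------------------
    cloud = seeding.seed_points(fibres, spacing=config.spacing, voxel_size=voxel_size)
    cloud = _subsample_fibres(cloud, config.max_fibres)
    seeding.write_point_cloud(cloud, out / "cloud.csv")
    meta["stages"]["seeding"] = {"n_points": len(cloud), "n_fibres": cloud.n_fibres, "spacing_um": config.spacing}
    logger.info("seeded %d points on %d fibres", len(cloud), cloud.n_fibres)

    # --- DVC over the load sequence --------------------------------------
    steps_metrics: list[pd.DataFrame] = []
    if len(vols) >= 2:
        params = dvc_mod.DvcParams(**{**config.dvc, "rng_seed": config.rng_seed + _SEED_DVC})
        incremental, cumulative = dvc_mod.run_sequence(vols, cloud, params)
        for k, (inc, cum) in enumerate(zip(incremental, cumulative)):
            inc.to_csv(out / f"disp_incr_step{k}.csv", index=False)
            cum.to_csv(out / f"disp_cum_step{k}.csv", index=False)
        conv = [float(i.converged.mean()) for i in incremental]
        meta["stages"]["dvc"] = {"n_steps": len(incremental), "frac_converged": conv}
        logger.info("DVC: %d step(s), convergence %s", len(incremental), conv)
        # --- metrics per step ---------------------------------------------
        for k, inc in enumerate(incremental):
            met, diag = metrics_mod.compute_metrics(cloud, displacements=inc, c_hat=config.c_hat, return_diagnostics=True)
            delta = metrics_mod.delta_metrics(cloud, inc, c_hat=config.c_hat)
            met = met.merge(delta[["n", "dk", "dtheta"]], on="n", how="left")
            met.to_csv(out / f"metrics_step{k}.csv", index=False)
            diag.to_csv(out / f"fit_diagnostics_step{k}.csv", index=False)
            steps_metrics.append(met)
        flagged = float(np.mean([m.flag.mean() for m in steps_metrics]))
        meta["stages"]["metrics"] = {"n_steps": len(steps_metrics), "frac_flagged": flagged}
    else:
        met, diag = metrics_mod.compute_metrics(cloud, c_hat=config.c_hat, return_diagnostics=True)
        met.to_csv(out / "metrics_step0.csv", index=False)
        diag.to_csv(out / "fit_diagnostics_step0.csv", index=False)
        steps_metrics.append(met)
        meta["stages"]["metrics"] = {"n_steps": 1, "frac_flagged": float(met.flag.mean())}

    # --- stats ------------------------------------------------------------
    n_lam = int(cloud.points["l"].max())
    grouped = [stats.group_points(m[~m.flag], region=config.region, n_lamellae=n_lam) for m in steps_metrics]
    stats.report(grouped, out / "report", make_plots=config.make_plots)
    meta["stages"]["stats"] = {"n_groups": int(grouped[0].groupby(["region", "depth"]).ngroups)}

    config.to_yaml(out / "config.yaml")
    (out / "run_meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return out
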