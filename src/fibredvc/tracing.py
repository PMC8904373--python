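"""Cylinder-template fibre enhancement and greedy centreline tracing.

Fibre-like structures are enhanced by correlating the volume against a
bright-core/suppressing-annulus cylinder template over a sampled hemisphere
of orientations (antipodal orientations are equivalent for correlation);
the per-voxel maximum zero-normalised correlation and its argmax direction
then drive a greedy bidirectional marching tracer.  Traced voxels are
suppressed so no two output polylines share a vertex.

The whole module is optional in the pipeline: externally traced
centrelines can be ingested from the fibre-table CSV instead (the package
accepts either route with identical downstream schema).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .fibres import FibrePolyline
from .volume import Volume

__all__ = ["CylinderTemplateParams", "TraceParams", "cylinder_correlate", "trace_fibres", "label_lamellae", "hemisphere_directions"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CylinderTemplateParams:
    """Cylinder-correlation template geometry (voxels / degrees)."""

    length_vox: int = 40
    angular_sampling_deg: float = 5.0
    mask_radius_vox: float = 5.0
    outer_radius_vox: float = 3.0
    erosion_vox: int = 8

    def validate(self) -> None:
        if not 0 < self.outer_radius_vox < self.mask_radius_vox:
            raise ValueError("need 0 < outer_radius_vox < mask_radius_vox")
        if self.length_vox < 3 * self.mask_radius_vox:
            raise ValueError("length_vox must be >= 3 x mask_radius_vox")
        if self.erosion_vox < self.mask_radius_vox:
            raise ValueError("erosion_vox must be >= mask_radius_vox (erode slightly more than the template)")
        if self.angular_sampling_deg <= 0:
            raise ValueError("angular_sampling_deg must be positive")


@dataclass(frozen=True)
class TraceParams:
    """Greedy tracing thresholds; scores are normalised correlations in [0, 1].

    Defaults keep the 0.8 continuation/start ratio of the reference tracing
    protocol on its own (undocumented) score scale.
    """

    min_start_score: float = 0.5
    min_continuation_score: float = 0.4
    step_vox: float = 1.5
    max_turn_deg: float = 30.0
    min_length_vox: float = 20.0

    def validate(self) -> None:
        if not 0 < self.min_continuation_score <= self.min_start_score <= 1:
            raise ValueError("need 0 < min_continuation_score <= min_start_score <= 1")
        if self.step_vox <= 0 or self.max_turn_deg <= 0 or self.min_length_vox < 0:
            raise ValueError("invalid marching parameters")


def hemisphere_directions(angular_sampling_deg: float) -> np.ndarray:
    """Unit directions covering one hemisphere at the given angular pitch.

    Polar bands from the pole (z axis) at ``angular_sampling_deg`` spacing,
    each band carrying enough azimuthal samples to keep the arc spacing at
    or below the pitch; ~1,300 directions at 5°.
    """
    step = np.radians(angular_sampling_deg)
    dirs = [(0.0, 0.0, 1.0)]
    n_bands = int(np.floor(np.pi / 2 / step + 1e-9))
    for b in range(1, n_bands + 1):
        pol = b * step
        # the equator band holds antipodal pairs: keep only half of it
        span = np.pi if abs(np.cos(pol)) < 1e-9 else 2 * np.pi
        n_az = max(1, int(np.ceil(span * np.sin(pol) / step)))
        for a in range(n_az):
            az = span * a / n_az
            dirs.append((np.sin(pol) * np.cos(az), np.sin(pol) * np.sin(az), np.cos(pol)))
    return np.asarray(dirs)


def _cylinder_template(direction: np.ndarray, params: CylinderTemplateParams):
    """Zero-mean unit-norm cylinder template and its support mask."""
    half_len = params.length_vox / 2.0
    r = int(np.ceil(np.sqrt(half_len**2 + params.mask_radius_vox**2)))
    # bounding box tight to the rotated cylinder
    ext = np.ceil(np.abs(direction) * half_len + params.mask_radius_vox).astype(int) + 1
    ax = [np.arange(-e, e + 1) for e in ext]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    axial = X * direction[0] + Y * direction[1] + Z * direction[2]
    rad2 = X * X + Y * Y + Z * Z - axial * axial
    support = (np.abs(axial) <= half_len) & (rad2 <= params.mask_radius_vox**2)
    core = support & (rad2 <= params.outer_radius_vox**2)
    tmpl = np.zeros(X.shape)
    tmpl[core] = 1.0
    tmpl[support] -= tmpl[support].mean()  # zero mean over the support
    norm = np.sqrt((tmpl[support] ** 2).sum())
    tmpl[support] /= norm
    return tmpl, support.astype(float)


def cylinder_correlate(vol: Volume, params: CylinderTemplateParams = CylinderTemplateParams()):
    """Per-voxel best cylinder correlation score and its orientation.

    Returns ``(score, directions)``: the maximum zero-normalised correlation
    over the sampled orientation set (zero for zero-variance neighbourhoods)
    and the argmax unit direction per voxel, shape (3, nx, ny, nz).  A shell
    of ``erosion_vox`` voxels at the volume boundary is zeroed to remove
    edge-correlation artefacts.
    """
    params.validate()
    data = vol.as_float()
    if min(data.shape) <= params.length_vox:
        raise ValueError(f"volume {data.shape} is not larger than the template length {params.length_vox}")
    data = (data - data.mean()) / max(data.std(), 1e-12)
    dirs = hemisphere_directions(params.angular_sampling_deg)
    logger.info("cylinder correlation over %d orientations", len(dirs))
    best = np.full(data.shape, -np.inf)
    best_idx = np.zeros(data.shape, dtype=np.int32)
    data2 = data * data
    for di, d in enumerate(dirs):
        tmpl, support = _cylinder_template(d, params)
        flip = tuple(slice(None, None, -1) for _ in range(3))
        num = fftconvolve(data, tmpl[flip], mode="same")
        m_v = fftconvolve(data, support[flip], mode="same")
        m_v2 = fftconvolve(data2, support[flip], mode="same")
        n_sup = support.sum()
        var = np.maximum(m_v2 - m_v * m_v / n_sup, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            score = np.where(var > 1e-9, num / np.sqrt(var), 0.0)
        upd = score > best
        best[upd] = score[upd]
        best_idx[upd] = di
    best = np.clip(best, -1.0, 1.0)
    e = params.erosion_vox
    eroded = np.zeros_like(best)
    eroded[e:-e, e:-e, e:-e] = best[e:-e, e:-e, e:-e]
    directions = dirs[best_idx].transpose(3, 0, 1, 2)
    return eroded, directions


def _march(score, directions, start, d0, params: TraceParams):
    """March one direction from a seed; returns visited float positions."""
    shape = score.shape
    pos = np.asarray(start, dtype=float)
    d = np.asarray(d0, dtype=float)
    pts = []
    cos_max = np.cos(np.radians(params.max_turn_deg))
    while True:
        nxt = pos + params.step_vox * d
        idx = np.rint(nxt).astype(int)
        if np.any(idx < 0) or np.any(idx >= shape):
            break
        sc = score[idx[0], idx[1], idx[2]]
        if sc < params.min_continuation_score:
            break
        d_new = directions[:, idx[0], idx[1], idx[2]].astype(float)
        if np.dot(d_new, d) < 0:
            d_new = -d_new  # antipodal sign disambiguation for continuity
        if np.dot(d_new, d) < cos_max:
            break
        pos = nxt
        d = d_new
        pts.append(pos.copy())
    return pts


def trace_fibres(
    score: np.ndarray,
    directions: np.ndarray,
    params: TraceParams = TraceParams(),
    voxel_size: float = 1.625,
) -> list[FibrePolyline]:
    """Greedy bidirectional tracing of correlation-line maxima.

    Seeds are taken in descending score order above ``min_start_score``;
    each trace marches ``step_vox`` along the local argmax direction in both
    senses, stopping on low score, a sharp turn, the volume edge or a voxel
    already claimed by an earlier trace.  Traced voxels are suppressed
    within the marching-step radius (smaller than half the bundle spacing,
    so neighbouring fibres survive), traces shorter than ``min_length_vox``
    are dropped, and the output is sorted by length descending with
    sequential fibre ids (lamella 0 = unassigned; see
    :func:`label_lamellae`).  Vertices are in µm.
    """
    params.validate()
    if score.size == 0:
        return []
    score = score.copy()
    seeds = np.argwhere(score >= params.min_start_score)
    if len(seeds) == 0:
        return []
    order = np.argsort(score[seeds[:, 0], seeds[:, 1], seeds[:, 2]])[::-1]
    seeds = seeds[order]
    suppress_r = max(2, int(np.ceil(params.step_vox)))
    out: list[FibrePolyline] = []
    for seed in seeds:
        sx, sy, sz = seed
        if score[sx, sy, sz] < params.min_start_score:
            continue  # suppressed by an earlier trace
        d0 = directions[:, sx, sy, sz].astype(float)
        fwd = _march(score, directions, seed.astype(float), d0, params)
        bwd = _march(score, directions, seed.astype(float), -d0, params)
        chain = bwd[::-1] + [seed.astype(float)] + fwd
        if len(chain) < 2:
            continue
        verts = np.asarray(chain)
        length = np.linalg.norm(np.diff(verts, axis=0), axis=1).sum()
        # suppress along the trace regardless of acceptance so that noise
        # blobs do not re-seed endlessly
        for p in verts:
            i0 = np.maximum(np.rint(p).astype(int) - suppress_r, 0)
            i1 = np.minimum(np.rint(p).astype(int) + suppress_r + 1, score.shape)
            score[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] = 0.0
        if length < params.min_length_vox:
            continue
        out.append(FibrePolyline(lamella=0, fibre=0, vertices=verts * voxel_size))
    out.sort(key=lambda fb: fb.length, reverse=True)
    for i, fb in enumerate(out):
        fb.fibre = i
    logger.info("traced %d fibres", len(out))
    return out


def label_lamellae(
    fibres: list[FibrePolyline],
    boundaries: np.ndarray | list[float],
    axis: int = 1,
) -> list[FibrePolyline]:
    """Assign each fibre the lamella bin holding the majority of its vertices.

    ``boundaries`` are strictly increasing positions (µm) along the AF-depth
    axis separating adjacent lamellae; an empty list puts everything in
    lamella 1 (labels increase inward, 1 = outermost).  Fibres outside all
    bins are assigned the nearest bin with a warning.
    """
    boundaries = np.asarray(boundaries, dtype=float)
    if len(boundaries) and np.any(np.diff(boundaries) <= 0):
        raise ValueError("lamella boundaries must be strictly increasing")
    for fb in fibres:
        coords = fb.vertices[:, axis]
        bins = np.digitize(coords, boundaries)  # 0..len(boundaries)
        counts = np.bincount(bins, minlength=len(boundaries) + 1)
        fb.lamella = int(np.argmax(counts)) + 1
    return fibres
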