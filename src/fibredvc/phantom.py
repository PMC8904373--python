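"""Synthetic fibrous-tomogram phantoms with exact ground truth.

The generator emulates the lamellar architecture of the annulus fibrosus as
it appears in reconstructed phase-contrast tomograms: stacked lamellar slabs
of parallel ~5 µm fibre bundles whose in-plane angle from the transverse
plane alternates in sign between adjacent lamellae.  Each bundle has a
Gaussian radial intensity profile and a smooth multiplicative intensity
modulation along its axis so that translation *along* the fibre is
observable by sub-volume correlation (without it, straight homogeneous
fibres would suffer the aperture problem).  Volumes are min–max scaled to
16-bit with additive Gaussian noise, matching the dynamic range of
down-sampled tomographic reconstructions.

Deformation fields are exact closed forms with exact inverses, so warped
volumes carry machine-precision displacement and strain ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace

import numpy as np
import pandas as pd

from .fibres import FibrePolyline, polylines_to_table
from .interpolate import warp_volume
from .volume import Volume

__all__ = [
    "PhantomConfig",
    "DeformationField",
    "RigidTranslation",
    "UniaxialStretch",
    "Bend",
    "RippleTranslation",
    "GroundTruth",
    "generate_volume",
    "deform_volume",
    "add_noise",
    "worst_case_noise_sd",
    "analytic_curve",
    "field_from_spec",
]

# intensity model (dimensionless, before 16-bit scaling)
_BACKGROUND = 0.2       # weakly scattering matrix, constant
_FIBRE_AMPLITUDE = 0.8  # core intensity above background before texture
_SCALE_LO = 4000.0      # 16-bit grey value of the dimmest noiseless voxel
_SCALE_HI = 60000.0     # ... and of the brightest (headroom left for noise)

# axial texture: random-phase sinusoid mixture, wavelengths in voxels
_TEXTURE_WAVELENGTHS = (5.0, 8.0, 13.0, 21.0)


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, texture and noise parameters of the synthetic volume.

    ``base_angles`` are per-lamella fibre angles in degrees measured from
    the transverse (x–y) plane; the default alternates ±30°, the range
    reported for annulus fibrosus fibre bundles.  ``fibre_radius`` is the
    bundle half-width (Gaussian FWHM = 2·radius ≈ 5 µm by default).
    """

    grid_shape: tuple[int, int, int] = (256, 256, 256)
    voxel_size: float = 1.625
    n_lamellae: int = 8
    lamella_thickness: float = 30.0
    fibre_spacing: float = 7.0
    fibre_radius: float = 2.5
    base_angles: tuple[float, ...] | None = None
    axial_texture_amplitude: float = 0.4
    noise_sd: float = 3000.0
    rng_seed: int = 0
    #: background-only margin (voxels) left on each side of the lamella stack
    depth_margin: int = 12

    def resolved_angles(self) -> tuple[float, ...]:
        if self.base_angles is not None:
            if len(self.base_angles) != self.n_lamellae:
                raise ValueError("base_angles length must equal n_lamellae")
            return tuple(float(a) for a in self.base_angles)
        return tuple(30.0 if i % 2 == 0 else -30.0 for i in range(self.n_lamellae))

    def validate(self) -> None:
        if any(s < 8 for s in self.grid_shape):
            raise ValueError("grid_shape axes must be >= 8 voxels")
        for name in ("voxel_size", "lamella_thickness", "fibre_spacing", "fibre_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_lamellae < 1:
            raise ValueError("n_lamellae must be >= 1")
        if self.fibre_radius / self.voxel_size < 1.0:
            raise ValueError("fibre_radius must be at least one voxel to be resolvable")
        if not 0.0 < self.axial_texture_amplitude <= 1.0:
            raise ValueError("axial_texture_amplitude must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        t_vox = self.lamella_thickness / self.voxel_size
        needed = self.n_lamellae * t_vox + 2 * self.depth_margin
        if needed > self.grid_shape[1]:
            raise ValueError(
                f"grid too small: {self.n_lamellae} lamellae of {t_vox:.1f} voxels plus margins "
                f"need {needed:.0f} voxels along y, have {self.grid_shape[1]}"
            )
        self.resolved_angles()


# ---------------------------------------------------------------------------
# Deformation fields: exact closed forms with exact inverses
# ---------------------------------------------------------------------------


class DeformationField:
    """A smooth, invertible displacement field over a voxel grid.

    All coordinates and displacements are in voxel units of the grid the
    field is defined on (``domain``).  Subclasses provide the forward
    displacement ``u(X)`` (material point at X maps to X + u(X)), the exact
    inverse map, and the analytic displacement gradient ``∂u_i/∂x_j`` used
    for ground-truth strain.
    """

    domain: tuple[int, int, int]

    def displacement(self, pts: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def inverse_map(self, pts: np.ndarray) -> np.ndarray:
        """Source coordinates X such that X + u(X) equals the given points."""
        raise NotImplementedError

    def gradient(self, pts: np.ndarray) -> np.ndarray:
        """(N, 3, 3) array G with G[n, i, j] = ∂u_i/∂x_j at point n."""
        raise NotImplementedError

    def check_invertible(self) -> None:
        """Raise ValueError for parameter sets outside the invertible range."""


class RigidTranslation(DeformationField):
    def __init__(self, translation, domain):
        self.t = np.asarray(translation, dtype=float).reshape(3)
        self.domain = tuple(domain)

    def displacement(self, pts):
        return np.broadcast_to(self.t, (len(pts), 3)).copy()

    def inverse_map(self, pts):
        return np.asarray(pts, dtype=float) - self.t

    def gradient(self, pts):
        return np.zeros((len(pts), 3, 3))


class UniaxialStretch(DeformationField):
    """Uniaxial stretch/compression about the grid centre with a barrel bulge.

    The loaded axis scales by ``stretch`` (λ < 1 compresses); the two
    lateral axes expand by a Poisson-like barrel profile
    ``λ_lat(h) = 1 + bulge·(1 − λ)·(1 − (h/H)²)`` where h is the signed
    offset along the loaded axis and H its half-extent.  Because the loaded
    coordinate maps independently of the lateral ones, the inverse is exact.
    """

    def __init__(self, stretch: float, domain, bulge: float = 0.0, axis: int = 2):
        if stretch <= 0:
            raise ValueError("stretch must be positive")
        self.stretch = float(stretch)
        self.bulge = float(bulge)
        self.axis = int(axis)
        self.domain = tuple(domain)
        self.centre = (np.asarray(domain, dtype=float) - 1.0) / 2.0
        self.half = (self.domain[self.axis] - 1) / 2.0
        self.check_invertible()

    def check_invertible(self) -> None:
        # lateral scale must stay positive over |h| <= H
        lat_min = 1.0 + self.bulge * (1.0 - self.stretch)
        lat_edge = 1.0
        if min(lat_min, lat_edge) <= 0:
            raise ValueError("bulge parameters make the lateral scale non-positive")

    def _lat_scale(self, h):
        return 1.0 + self.bulge * (1.0 - self.stretch) * (1.0 - (h / self.half) ** 2)

    def displacement(self, pts):
        pts = np.asarray(pts, dtype=float)
        rel = pts - self.centre
        h = rel[:, self.axis]
        u = np.zeros_like(rel)
        lat = self._lat_scale(h)
        for ax in range(3):
            if ax == self.axis:
                u[:, ax] = (self.stretch - 1.0) * h
            else:
                u[:, ax] = (lat - 1.0) * rel[:, ax]
        return u

    def inverse_map(self, pts):
        pts = np.asarray(pts, dtype=float)
        rel = pts - self.centre
        src = np.empty_like(rel)
        h = rel[:, self.axis] / self.stretch
        src[:, self.axis] = h
        lat = self._lat_scale(h)
        for ax in range(3):
            if ax != self.axis:
                src[:, ax] = rel[:, ax] / lat
        return src + self.centre

    def gradient(self, pts):
        pts = np.asarray(pts, dtype=float)
        rel = pts - self.centre
        h = rel[:, self.axis]
        g = np.zeros((len(pts), 3, 3))
        lat = self._lat_scale(h)
        dlat_dh = self.bulge * (1.0 - self.stretch) * (-2.0 * h / self.half**2)
        for ax in range(3):
            if ax == self.axis:
                g[:, ax, ax] = self.stretch - 1.0
            else:
                g[:, ax, ax] = lat - 1.0
                g[:, ax, self.axis] = dlat_dh * rel[:, ax]
        return g


class Bend(DeformationField):
    """Quadratic bending: height displaced by ``curvature/2 · (x − x0)²``.

    Adds curvature ``curvature`` (per voxel) about the y axis.  The height
    perturbation depends only on x, so the map inverts exactly.
    """

    def __init__(self, curvature: float, domain):
        self.c = float(curvature)
        self.domain = tuple(domain)
        self.x0 = (domain[0] - 1) / 2.0

    def displacement(self, pts):
        pts = np.asarray(pts, dtype=float)
        u = np.zeros_like(pts)
        u[:, 2] = 0.5 * self.c * (pts[:, 0] - self.x0) ** 2
        return u

    def inverse_map(self, pts):
        pts = np.asarray(pts, dtype=float)
        src = pts.copy()
        src[:, 2] -= 0.5 * self.c * (pts[:, 0] - self.x0) ** 2
        return src

    def gradient(self, pts):
        pts = np.asarray(pts, dtype=float)
        g = np.zeros((len(pts), 3, 3))
        g[:, 2, 0] = self.c * (pts[:, 0] - self.x0)
        return g


class RippleTranslation(DeformationField):
    """Rigid translation plus a low-amplitude sinusoidal height perturbation.

    ``u = t + (0, 0, A·sin(2πx/λ + φx)·sin(2πy/λ + φy))``.  The in-plane
    components are constant, so the inverse is exact.  Used as the "known
    smooth sub-voxel field" in tracking-accuracy studies.
    """

    def __init__(self, translation, domain, amplitude: float = 0.2, wavelength: float = 120.0, phases=(0.7, 1.9)):
        self.t = np.asarray(translation, dtype=float).reshape(3)
        self.A = float(amplitude)
        self.wl = float(wavelength)
        self.phases = tuple(phases)
        self.domain = tuple(domain)

    def _ripple(self, x, y):
        k = 2.0 * np.pi / self.wl
        return self.A * np.sin(k * x + self.phases[0]) * np.sin(k * y + self.phases[1])

    def displacement(self, pts):
        pts = np.asarray(pts, dtype=float)
        u = np.broadcast_to(self.t, pts.shape).copy()
        u[:, 2] += self._ripple(pts[:, 0], pts[:, 1])
        return u

    def inverse_map(self, pts):
        pts = np.asarray(pts, dtype=float)
        src = pts - self.t
        src[:, 2] -= self._ripple(src[:, 0], src[:, 1])
        return src

    def gradient(self, pts):
        pts = np.asarray(pts, dtype=float)
        k = 2.0 * np.pi / self.wl
        g = np.zeros((len(pts), 3, 3))
        g[:, 2, 0] = self.A * k * np.cos(k * pts[:, 0] + self.phases[0]) * np.sin(k * pts[:, 1] + self.phases[1])
        g[:, 2, 1] = self.A * k * np.sin(k * pts[:, 0] + self.phases[0]) * np.cos(k * pts[:, 1] + self.phases[1])
        return g


def field_from_spec(spec: str, domain) -> DeformationField:
    """Parse a CLI-style field spec, e.g. ``rigid:3,-2,1`` or ``stretch:0.98,0.3``."""
    kind, _, rest = spec.partition(":")
    vals = [float(v) for v in rest.split(",")] if rest else []
    if kind in {"rigid", "rigid_translation"}:
        if len(vals) != 3:
            raise ValueError("rigid field needs 3 components, e.g. rigid:3,-2,1")
        return RigidTranslation(vals, domain)
    if kind in {"stretch", "uniaxial_compression_bulge"}:
        bulge = vals[1] if len(vals) > 1 else 0.0
        axis = int(vals[2]) if len(vals) > 2 else 2
        return UniaxialStretch(vals[0], domain, bulge=bulge, axis=axis)
    if kind == "bend":
        return Bend(vals[0], domain)
    if kind == "ripple":
        amp = vals[3] if len(vals) > 3 else 0.2
        wl = vals[4] if len(vals) > 4 else 120.0
        return RippleTranslation(vals[:3], domain, amplitude=amp, wavelength=wl)
    raise ValueError(f"unknown deformation field kind {kind!r}")


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Exact answers for a phantom, optionally bound to a deformation field."""

    fibre_table: pd.DataFrame
    config: PhantomConfig
    field: DeformationField | None = None
    polylines: list[FibrePolyline] = dc_field(default_factory=list, repr=False)

    def with_field(self, field: DeformationField) -> "GroundTruth":
        return replace(self, field=field)

    def displacement_at(self, pts_vox: np.ndarray) -> np.ndarray:
        pts_vox = np.atleast_2d(np.asarray(pts_vox, dtype=float))
        if self.field is None:
            return np.zeros_like(pts_vox)
        return self.field.displacement(pts_vox)

    def fibre_strain_at(self, pts_vox: np.ndarray, tangents: np.ndarray) -> np.ndarray:
        """Exact Lagrange strain along the given unit directions.

        Computed from the deformation gradient F = I + ∇u as t·E·t with
        E = (FᵀF − I)/2; identically zero for rigid fields.
        """
        pts_vox = np.atleast_2d(np.asarray(pts_vox, dtype=float))
        t = np.atleast_2d(np.asarray(tangents, dtype=float))
        t = t / np.linalg.norm(t, axis=1, keepdims=True)
        if self.field is None:
            return np.zeros(len(pts_vox))
        G = self.field.gradient(pts_vox)
        F = G + np.eye(3)[None]
        E = 0.5 * (np.einsum("nki,nkj->nij", F, F) - np.eye(3)[None])
        return np.einsum("ni,nij,nj->n", t, E, t)


# ---------------------------------------------------------------------------
# Volume generation
# ---------------------------------------------------------------------------


def _lamella_slabs(config: PhantomConfig) -> list[tuple[int, int]]:
    """Half-open voxel ranges [y0, y1) of each lamella along the depth axis."""
    t_vox = config.lamella_thickness / config.voxel_size
    slabs = []
    for i in range(config.n_lamellae):
        y0 = config.depth_margin + i * t_vox
        slabs.append((int(round(y0)), int(round(y0 + t_vox))))
    return slabs


def lamella_boundaries(config: PhantomConfig) -> np.ndarray:
    """Positions (µm, along the depth axis y) separating adjacent lamellae."""
    slabs = _lamella_slabs(config)
    return np.array([y1 for (y0, y1) in slabs[:-1]], dtype=float) * config.voxel_size


def generate_volume(config: PhantomConfig) -> tuple[Volume, GroundTruth]:
    """Build the phantom volume and its exact fibre-centreline ground truth.

    Lamellae are planar slabs stacked along y (the AF depth axis); within
    lamella ``i`` all fibres are parallel lines in the x–z plane at angle
    ``base_angles[i]`` from the transverse plane, on a square lattice of
    pitch ``fibre_spacing`` in the cross-fibre directions.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    nx, ny, nz = config.grid_shape
    vs = config.voxel_size
    sigma = (config.fibre_radius / vs) / np.sqrt(2.0 * np.log(2.0))  # FWHM = 2·radius
    pitch = config.fibre_spacing / vs
    angles = config.resolved_angles()
    slabs = _lamella_slabs(config)

    intensity = np.full(config.grid_shape, _BACKGROUND, dtype=np.float32)
    polylines: list[FibrePolyline] = []
    n_waves = len(_TEXTURE_WAVELENGTHS)
    # fixed mixture weights, RMS ~ 0.7 before clipping
    wave_weights = np.array([0.5, 0.45, 0.35, 0.25])
    wave_weights = wave_weights / np.sqrt((wave_weights**2).sum() / 2.0) * 0.7

    xs = np.arange(nx, dtype=np.float32)
    zs = np.arange(nz, dtype=np.float32)
    fibre_counter = 0

    for lam_idx, ((y0, y1), ang) in enumerate(zip(slabs, angles), start=1):
        th = np.deg2rad(ang)
        u = np.array([np.cos(th), 0.0, np.sin(th)])  # fibre direction
        v = np.array([-np.sin(th), 0.0, np.cos(th)])  # in-plane cross-fibre direction
        # cross-fibre coordinate b and axial coordinate a over the slab
        A = xs[:, None] * u[0] + zs[None, :] * u[2]   # (nx, nz)
        B = xs[:, None] * v[0] + zs[None, :] * v[2]
        # fibre lattice: rows across lamella thickness (c = y), columns in b
        n_rows = max(1, int(np.floor((y1 - y0) / pitch)))
        row_c = y0 + ((y1 - y0) - (n_rows - 1) * pitch) / 2.0 + np.arange(n_rows) * pitch
        j_min = int(np.floor(B.min() / pitch)) - 1
        j_max = int(np.ceil(B.max() / pitch)) + 1
        n_cols = j_max - j_min + 1
        phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_cols, n_rows, n_waves)).astype(np.float32)

        J = np.rint(B / pitch).astype(np.int32) - j_min      # nearest column index, (nx, nz)
        db = (B - (J + j_min) * pitch).astype(np.float32)
        prof_b = np.exp(-0.5 * (db / sigma) ** 2)            # (nx, nz)

        # axial texture per column/row evaluated at the in-plane axial coordinate
        slab = intensity[:, y0:y1, :]
        ys_local = np.arange(y0, y1, dtype=np.float32)
        K = np.clip(np.rint((ys_local - row_c[0]) / pitch).astype(np.int32), 0, n_rows - 1)  # (ny_slab,)
        dc = ys_local - row_c[K]                                                             # (ny_slab,)
        prof_c = np.exp(-0.5 * (dc / sigma) ** 2)                                            # (ny_slab,)

        tex = np.zeros((nx, nz), dtype=np.float32)
        for m, wl in enumerate(_TEXTURE_WAVELENGTHS):
            # phase looked up per nearest fibre column; rows share texture phase
            # only through their own k index below
            tex_m = np.sin((2.0 * np.pi / wl) * A + phases[J, 0, m])
            tex += wave_weights[m] * tex_m
        # per-row phase offset: rotate texture by adding a row-dependent phase
        # for row k, reuse mixture but with the row's phase table
        for k in range(n_rows):
            if k == 0:
                tex_k = tex
            else:
                tex_k = np.zeros((nx, nz), dtype=np.float32)
                for m, wl in enumerate(_TEXTURE_WAVELENGTHS):
                    tex_k += wave_weights[m] * np.sin((2.0 * np.pi / wl) * A + phases[J, k, m])
            mod = 1.0 + config.axial_texture_amplitude * np.clip(tex_k, -1.0, 1.0)
            rows_here = np.nonzero(K == k)[0]
            for yy in rows_here:
                contrib = _FIBRE_AMPLITUDE * mod * prof_b * prof_c[yy]
                np.maximum(slab[:, yy, :], _BACKGROUND + contrib, out=slab[:, yy, :])

        # ground-truth centrelines: line through (b = j·pitch, y = row_c[k])
        a_lo, a_hi = _line_range_in_box(u, v, nx, nz)
        for j in range(j_min, j_max + 1):
            b = j * pitch
            seg = _clip_line(u, v, b, nx, nz)
            if seg is None:
                continue
            a0, a1 = seg
            if a1 - a0 < 20.0:  # skip corner slivers shorter than ~20 voxels
                continue
            n_verts = max(2, int(np.ceil((a1 - a0) / 4.0)) + 1)
            a_samples = np.linspace(a0, a1, n_verts)
            for k in range(n_rows):
                pts = np.empty((n_verts, 3))
                pts[:, 0] = a_samples * u[0] + b * v[0]
                pts[:, 1] = row_c[k]
                pts[:, 2] = a_samples * u[2] + b * v[2]
                polylines.append(
                    FibrePolyline(
                        lamella=lam_idx,
                        fibre=fibre_counter,
                        vertices=pts * vs,
                        true_tangent=np.broadcast_to(u, (n_verts, 3)).copy(),
                        true_curvature=np.zeros(n_verts),
                    )
                )
                fibre_counter += 1

    # 16-bit scaling of the noiseless construction, then additive noise
    lo, hi = float(intensity.min()), float(intensity.max())
    scaled = (_SCALE_LO + (intensity - lo) / (hi - lo) * (_SCALE_HI - _SCALE_LO)).astype(np.float32)
    if config.noise_sd > 0:
        scaled = scaled + rng.normal(0.0, config.noise_sd, size=scaled.shape).astype(np.float32)
    data = np.clip(np.rint(scaled), 0, 65535).astype(np.uint16)

    truth = GroundTruth(fibre_table=polylines_to_table(polylines), config=config, polylines=polylines)
    return Volume(data, voxel_size=vs), truth


def _line_range_in_box(u, v, nx, nz):
    return -float(nx + nz), float(nx + nz)


def _clip_line(u, v, b, nx, nz):
    """Axial-parameter interval for which the line x = a·u + b·v stays in the x–z box."""
    lo, hi = _line_range_in_box(u, v, nx, nz)
    for comp, n in ((0, nx), (2, nz)):
        du = u[comp]
        x0 = b * v[comp]
        if abs(du) < 1e-12:
            if not (0.0 <= x0 <= n - 1):
                return None
            continue
        t1 = (0.0 - x0) / du
        t2 = ((n - 1) - x0) / du
        lo = max(lo, min(t1, t2))
        hi = min(hi, max(t1, t2))
    if hi <= lo:
        return None
    return lo, hi


def deform_volume(vol: Volume, field: DeformationField, fill: float | None = None) -> Volume:
    """Resample a volume under the inverse map of a deformation field.

    Material at X moves to X + u(X); the output image at voxel Y is the
    tricubic sample of the input at ``field.inverse_map(Y)``.  Voxels whose
    interpolation stencil leaves the input domain are set to ``fill``
    (default: median intensity of the boundary faces, i.e. background) and
    flagged invalid.
    """
    if tuple(field.domain) != tuple(vol.shape):
        raise ValueError(f"field domain {field.domain} does not match volume shape {vol.shape}")
    field.check_invertible()
    nx, ny, nz = vol.shape
    if fill is None:
        faces = [vol.data[0], vol.data[-1], vol.data[:, 0], vol.data[:, -1], vol.data[:, :, 0], vol.data[:, :, -1]]
        fill = float(np.median(np.concatenate([f.ravel() for f in faces])))
    grid = np.stack(
        np.meshgrid(np.arange(nx, dtype=float), np.arange(ny, dtype=float), np.arange(nz, dtype=float), indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    src = field.inverse_map(grid)
    coords = tuple(src[:, ax].reshape(vol.shape) for ax in range(3))
    out, valid = warp_volume(vol.as_float(), coords, fill=fill)
    if np.issubdtype(vol.data.dtype, np.integer):
        info = np.iinfo(vol.data.dtype)
        out = np.clip(np.rint(out), info.min, info.max).astype(vol.data.dtype)
    else:
        out = out.astype(vol.data.dtype)
    return Volume(out, vol.voxel_size, valid=valid)


def add_noise(vol: Volume, sd: float, rng: np.random.Generator) -> Volume:
    """Additive Gaussian greyscale noise, clipped to the dtype range."""
    if sd < 0:
        raise ValueError("noise sd must be >= 0")
    noisy = vol.as_float() + rng.normal(0.0, sd, size=vol.shape)
    if np.issubdtype(vol.data.dtype, np.integer):
        info = np.iinfo(vol.data.dtype)
        noisy = np.clip(np.rint(noisy), info.min, info.max).astype(vol.data.dtype)
    else:
        noisy = noisy.astype(vol.data.dtype)
    return Volume(noisy, vol.voxel_size, valid=vol.valid)


def empty_region(vol: Volume, config: PhantomConfig) -> np.ndarray:
    """Greyscale values of the background-only depth margin of a phantom."""
    m = config.depth_margin
    if m < 3:
        raise ValueError("phantom has no background margin to measure")
    return vol.data[:, : m - 2, :].ravel()


def worst_case_noise_sd(vol: Volume, truth: GroundTruth) -> float:
    """Worst-case added-noise level for the noise-robustness study.

    Mirrors how such studies are run on real scan series: the noise
    standard deviation is measured in a structure-free (air/background)
    region of the volume, and that measured level is added on top of the
    already-noisy reference — doubling the effective imaging noise.  For
    the phantom the structure-free region is its background depth margin.
    """
    return float(np.std(empty_region(vol, truth.config).astype(np.float64)))


def fibre_background_contrast(vol: Volume, truth: GroundTruth) -> tuple[float, float]:
    """(contrast, CNR): mean grey at true centrelines minus background mean,
    and its ratio to the background noise sd."""
    bg_vals = empty_region(vol, truth.config).astype(np.float64)
    bg = float(bg_vals.mean())
    pts = truth.fibre_table[["x", "y", "z"]].to_numpy() / vol.voxel_size
    idx = np.rint(pts).astype(int)
    ok = np.all((idx >= 0) & (idx < np.array(vol.shape)), axis=1)
    idx = idx[ok]
    core = float(np.mean(vol.data[idx[:, 0], idx[:, 1], idx[:, 2]]))
    contrast = core - bg
    sd = float(bg_vals.std())
    return contrast, contrast / sd if sd > 0 else np.inf


# ---------------------------------------------------------------------------
# Analytic test curves
# ---------------------------------------------------------------------------


def analytic_curve(kind: str, parameters: dict, n_points: int, spacing: float) -> FibrePolyline:
    """Exactly sampled space curves with attached curvature/tangent truth.

    ``kind`` is one of ``line`` (params: ``start``, ``direction``),
    ``circle`` (``radius``, optional ``centre``; lies in the x–z plane) or
    ``helix`` (``radius`` r, ``pitch`` c for the arc form
    (r cos u, r sin u, c u); curvature r/(r²+c²)).  Vertices are placed at
    exact arc-length multiples of ``spacing`` (µm).
    """
    if n_points < 2:
        raise ValueError("need at least 2 points")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    s = np.arange(n_points) * spacing
    if kind == "line":
        d = np.asarray(parameters.get("direction", (1.0, 0.0, 0.0)), dtype=float)
        d = d / np.linalg.norm(d)
        p0 = np.asarray(parameters.get("start", (0.0, 0.0, 0.0)), dtype=float)
        verts = p0[None] + s[:, None] * d[None]
        tangents = np.broadcast_to(d, (n_points, 3)).copy()
        curv = np.zeros(n_points)
    elif kind == "circle":
        r = float(parameters["radius"])
        if r <= 0:
            raise ValueError("circle radius must be positive")
        c0 = np.asarray(parameters.get("centre", (0.0, 0.0, 0.0)), dtype=float)
        phi = s / r
        verts = c0[None] + np.stack([r * np.cos(phi), np.zeros_like(phi), r * np.sin(phi)], axis=1)
        tangents = np.stack([-np.sin(phi), np.zeros_like(phi), np.cos(phi)], axis=1)
        curv = np.full(n_points, 1.0 / r)
    elif kind == "helix":
        r = float(parameters["radius"])
        c = float(parameters["pitch"])
        if r <= 0:
            raise ValueError("helix radius must be positive")
        denom = np.sqrt(r * r + c * c)
        uu = s / denom
        verts = np.stack([r * np.cos(uu), r * np.sin(uu), c * uu], axis=1)
        tangents = np.stack([-r * np.sin(uu), r * np.cos(uu), np.full_like(uu, c)], axis=1) / denom
        curv = np.full(n_points, r / (r * r + c * c))
    else:
        raise ValueError(f"unknown curve kind {kind!r}")
    return FibrePolyline(lamella=1, fibre=0, vertices=verts, true_tangent=tangents, true_curvature=curv)
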