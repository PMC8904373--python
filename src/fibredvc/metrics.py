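"""Per-fibre space-curve fitting and per-point fibre metrics.

Each fibre's seeded points are fitted with three independent third-order
polynomials in arc length s — fx(s), fy(s), fz(s) — weighted by the inverse
of each point's DVC matching residual, so poorly tracked points carry
little weight.  From the fitted curves every point gets:

- the unit tangent ``t = f'(s)/|f'(s)|``,
- the Frenet–Serret curvature ``k = |f'(s) × f''(s)| / |f'(s)|³``,
- the orientation θ: the elevation of the tangent from the transverse
  (x–y) plane, ``tan θ = |t × a| / (t · a)`` with ``a = t{z=0}``, mapped to
  [0°, 180°) so the two alternating fibre families of adjacent lamellae
  fall on opposite sides of 90°,
- the along-fibre displacement gradient ``m = d(u,v,w)/ds · t`` from a
  second weighted cubic fit of the displacements against s,
- the Lagrange strain ``L = m + m²/2`` (equal to (λ² − 1)/2 for a uniform
  stretch λ along the fibre).

Fits are performed in numpy's scaled polynomial domain for conditioning and
converted back to raw-s coefficients for storage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial import Polynomial

from .seeding import FibrePointCloud

__all__ = [
    "SpaceCurveFit",
    "fit_space_curve",
    "tangent_at",
    "curvature_at",
    "orientation_at",
    "displacement_gradient_at",
    "lagrange_strain",
    "compute_metrics",
    "delta_metrics",
    "residual_weights",
]

logger = logging.getLogger(__name__)

#: floor applied to DVC residuals before inverting into fit weights
WEIGHT_EPS = 1e-6
#: below this in-plane tangent norm a fibre counts as vertical (θ = 90°)
VERTICAL_EPS = 1e-6

METRICS_COLUMNS = ["n", "l", "f", "p", "s", "tx", "ty", "tz", "k", "theta", "m", "L", "flag"]


@dataclass
class SpaceCurveFit:
    """Cubic space-curve fit of one fibre: x, y, z each cubic in s (µm).

    ``coeffs`` holds the raw-s polynomial coefficients per axis in
    descending powers (p1·s³ + p2·s² + p3·s + p4), matching the usual
    parametric space-curve notation.
    """

    lamella: int
    fibre: int
    coeffs: np.ndarray  # (3, 4), descending powers
    r2_axis: np.ndarray  # per-axis weighted R²
    r2: float  # combined, variance-weighted
    mean_residual_vox: float
    s_range: tuple[float, float]
    _polys: list[Polynomial] | None = None

    def _axis_polys(self) -> list[Polynomial]:
        if self._polys is None:
            self._polys = [Polynomial(self.coeffs[ax, ::-1]) for ax in range(3)]
        return self._polys

    def position(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        return np.stack([p(s) for p in self._axis_polys()], axis=-1)

    def derivative(self, s, order: int = 1) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        return np.stack([p.deriv(order)(s) for p in self._axis_polys()], axis=-1)

    def in_range(self, s, spacing: float) -> np.ndarray:
        """Points within the fitted range ± one spacing of extrapolation."""
        s = np.asarray(s, dtype=float)
        return (s >= self.s_range[0] - spacing) & (s <= self.s_range[1] + spacing)


def residual_weights(residuals: np.ndarray, eps: float = WEIGHT_EPS) -> np.ndarray:
    """Inverse-residual fit weights ``w = 1 / max(residual, eps)``."""
    return 1.0 / np.maximum(np.asarray(residuals, dtype=float), eps)


def _weighted_cubic(s: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[Polynomial, float]:
    """One weighted cubic fit; returns the polynomial (raw-s domain kept via
    numpy's domain mapping) and the weighted R²."""
    sqrt_w = np.sqrt(w)
    poly = Polynomial.fit(s, y, deg=3, w=sqrt_w)
    resid = y - poly(s)
    ybar = np.average(y, weights=w)
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    ss_res = float(np.sum(w * resid**2))
    r2 = 1.0 if ss_tot <= 1e-300 else 1.0 - ss_res / ss_tot
    return poly, r2


def fit_space_curve(
    s: np.ndarray,
    positions: np.ndarray,
    weights: np.ndarray | None = None,
    lamella: int = 0,
    fibre: int = 0,
    voxel_size: float = 1.625,
) -> SpaceCurveFit:
    """Weighted least-squares cubic fits of x, y, z against arc length s.

    ``weights`` are typically :func:`residual_weights` of the DVC residuals;
    unit weights if omitted.  Requires at least 4 points with distinct s.
    """
    s = np.asarray(s, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if len(s) < 4:
        raise ValueError(f"fibre (l={lamella}, f={fibre}): need >= 4 points for a cubic fit, got {len(s)}")
    if len(np.unique(s)) < 4:
        raise ValueError(f"fibre (l={lamella}, f={fibre}): coincident s values make the cubic fit rank-deficient")
    w = np.ones_like(s) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")

    coeffs = np.empty((3, 4))
    r2_axis = np.empty(3)
    fitted = np.empty_like(positions)
    ss_tot = np.empty(3)
    for ax in range(3):
        poly, r2_axis[ax] = _weighted_cubic(s, positions[:, ax], w)
        c = poly.convert().coef  # ascending, raw s
        c = np.pad(c, (0, 4 - len(c)))
        coeffs[ax] = c[::-1]
        fitted[:, ax] = poly(s)
        ybar = np.average(positions[:, ax], weights=w)
        ss_tot[ax] = np.sum(w * (positions[:, ax] - ybar) ** 2)

    total = ss_tot.sum()
    r2 = float(np.sum(ss_tot * r2_axis) / total) if total > 1e-300 else 1.0
    mean_residual = float(np.mean(np.linalg.norm(positions - fitted, axis=1))) / voxel_size
    return SpaceCurveFit(
        lamella=lamella,
        fibre=fibre,
        coeffs=coeffs,
        r2_axis=r2_axis,
        r2=r2,
        mean_residual_vox=mean_residual,
        s_range=(float(s.min()), float(s.max())),
    )


def tangent_at(fit: SpaceCurveFit, s) -> np.ndarray:
    """Unit tangent(s) of the fitted curve; NaN where ``|f'|`` degenerates."""
    d1 = fit.derivative(s, 1)
    norm = np.linalg.norm(d1, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore"):
        t = np.where(norm > 1e-12, d1 / norm, np.nan)
    return t


def curvature_at(fit: SpaceCurveFit, s) -> np.ndarray:
    """Frenet–Serret curvature ``|f' × f''| / |f'|³`` in µm⁻¹."""
    d1 = fit.derivative(s, 1)
    d2 = fit.derivative(s, 2)
    cross = np.cross(d1, d2)
    norm1 = np.linalg.norm(d1, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(norm1 > 1e-12, np.linalg.norm(cross, axis=-1) / norm1**3, np.nan)
    return k


def orientation_at(t: np.ndarray, c_hat=(1.0, 0.0, 0.0)) -> np.ndarray:
    """Orientation θ in degrees, [0°, 180°).

    The raw angle is the unsigned elevation of the tangent from the
    transverse plane (``tan θ = |t × a| / t·a`` with ``a = t{z=0}``, giving
    [0°, 90°]).  To separate the two alternating fibre families the tangent
    is first flipped so its in-plane component points along the global
    circumferential direction ``c_hat``; tangents then rising out of the
    transverse plane keep the raw angle and falling ones map to 180° − raw.
    Vertical tangents (in-plane norm < 1e-6) return exactly 90°.
    """
    t = np.atleast_2d(np.asarray(t, dtype=float))
    norms = np.linalg.norm(t, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("tangents must be unit vectors")
    c = np.asarray(c_hat, dtype=float)
    c = c / np.linalg.norm(c)
    # flip each tangent into the +c_hat half-space (fibres are unoriented);
    # tangents perpendicular to c_hat tie-break on the in-plane perpendicular
    # so antipodal tangents always land on the same family
    dot1 = t[:, :2] @ c[:2]
    dot2 = t[:, :2] @ np.array([-c[1], c[0]])
    primary = np.where(np.abs(dot1) > 1e-12, dot1, dot2)
    sign = np.where(primary < 0, -1.0, 1.0)
    tf = t * sign[:, None]
    a_norm = np.linalg.norm(tf[:, :2], axis=1)
    raw = np.degrees(np.arctan2(np.abs(tf[:, 2]), a_norm))
    theta = np.where(tf[:, 2] >= 0, raw, 180.0 - raw)
    theta = np.where(a_norm < VERTICAL_EPS, 90.0, theta)
    theta = np.where(theta >= 180.0, theta - 180.0, theta)  # half-open [0, 180)
    return theta if theta.shape[0] > 1 else theta.reshape(-1)


def displacement_gradient_at(
    s: np.ndarray,
    displacements_um: np.ndarray,
    tangents: np.ndarray,
    weights: np.ndarray | None = None,
    eval_s: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Along-fibre displacement gradient ``m = (u', v', w') · t``.

    ``displacements_um`` are the per-point DVC displacements in µm; each
    component is fitted with a weighted cubic in s and differentiated, so m
    is dimensionless (µm/µm).  Returns ``(m at eval_s, combined fit R²)``.
    """
    s = np.asarray(s, dtype=float)
    disp = np.asarray(displacements_um, dtype=float)
    if len(s) < 4:
        raise ValueError("need >= 4 displacement records for the cubic displacement fit")
    w = np.ones_like(s) if weights is None else np.asarray(weights, dtype=float)
    eval_s = s if eval_s is None else np.asarray(eval_s, dtype=float)
    grads = np.empty((len(eval_s), 3))
    r2s = np.empty(3)
    ss_tot = np.empty(3)
    for ax in range(3):
        poly, r2s[ax] = _weighted_cubic(s, disp[:, ax], w)
        grads[:, ax] = poly.deriv()(eval_s)
        ybar = np.average(disp[:, ax], weights=w)
        ss_tot[ax] = np.sum(w * (disp[:, ax] - ybar) ** 2)
    total = ss_tot.sum()
    disp_r2 = float(np.sum(ss_tot * r2s) / total) if total > 1e-300 else 1.0
    m = np.einsum("ij,ij->i", grads, np.atleast_2d(tangents))
    return m, disp_r2


def lagrange_strain(m) -> np.ndarray:
    """Lagrange strain along the fibre: ``L = m + m²/2``."""
    m = np.asarray(m, dtype=float)
    return m + 0.5 * m * m


def compute_metrics(
    cloud: FibrePointCloud,
    displacements: pd.DataFrame | None = None,
    c_hat=(1.0, 0.0, 0.0),
    return_diagnostics: bool = False,
):
    """Fit every fibre and evaluate all per-point metrics.

    When a DVC displacement table is given (columns ``n, u, v, w, residual,
    converged``), fits are weighted by inverse residual, only converged
    points enter the displacement fit, and m and L are emitted; otherwise
    geometry-only metrics (t, k, θ) are computed with unit weights.  The
    first and last point of each fibre are flagged (polynomial derivatives
    are least constrained there), as are points with degenerate tangents.
    """
    disp = None
    if displacements is not None:
        disp = displacements.set_index("n")
    rows = []
    diags = []
    for (lam, fib), grp in cloud.fibre_groups():
        s = grp["s"].to_numpy()
        pos = grp[["x", "y", "z"]].to_numpy()
        ids = grp["n"].to_numpy()
        if len(s) < 4:
            logger.info("fibre (l=%d, f=%d): %d point(s) after filtering, skipping", lam, fib, len(s))
            continue
        if disp is not None:
            res = disp.loc[ids, "residual"].to_numpy()
            w = residual_weights(res)
        else:
            w = np.ones_like(s)
        fit = fit_space_curve(s, pos, w, lamella=int(lam), fibre=int(fib), voxel_size=cloud.voxel_size)
        t = tangent_at(fit, s)
        k = curvature_at(fit, s)
        theta = orientation_at(t, c_hat)
        m = np.full(len(s), np.nan)
        L = np.full(len(s), np.nan)
        disp_r2 = np.nan
        if disp is not None:
            conv = disp.loc[ids, "converged"].to_numpy().astype(bool)
            if conv.sum() >= 4:
                uvw_vox = disp.loc[ids, ["u", "v", "w"]].to_numpy()[conv]
                uvw_um = uvw_vox * cloud.voxel_size
                m, disp_r2 = displacement_gradient_at(s[conv], uvw_um, t, weights=w[conv], eval_s=s)
                L = lagrange_strain(m)
            else:
                logger.info("fibre (l=%d, f=%d): only %d converged points, skipping strain", lam, fib, conv.sum())
        flag = np.zeros(len(s), dtype=bool)
        flag[0] = flag[-1] = True  # end effects
        flag |= ~np.isfinite(t).all(axis=1)
        rows.append(
            pd.DataFrame(
                {
                    "n": ids,
                    "l": int(lam),
                    "f": int(fib),
                    "p": grp["p"].to_numpy(),
                    "s": s,
                    "tx": t[:, 0],
                    "ty": t[:, 1],
                    "tz": t[:, 2],
                    "k": k,
                    "theta": theta,
                    "m": m,
                    "L": L,
                    "flag": flag,
                }
            )
        )
        diags.append(
            {
                "l": int(lam),
                "f": int(fib),
                "R2": fit.r2,
                "mean_residual": fit.mean_residual_vox,
                "disp_R2": disp_r2,
            }
        )
    metrics = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=METRICS_COLUMNS)
    )
    if return_diagnostics:
        return metrics, pd.DataFrame(diags)
    return metrics


def wrap_angle_difference(dtheta: np.ndarray) -> np.ndarray:
    """Wrap orientation changes to (−90°, 90°] (the smaller equivalent rotation)."""
    w = (np.asarray(dtheta, dtype=float) + 90.0) % 180.0 - 90.0
    return np.where(np.isclose(w, -90.0), 90.0, w)


def delta_metrics(
    cloud: FibrePointCloud,
    displacements: pd.DataFrame,
    c_hat=(1.0, 0.0, 0.0),
) -> pd.DataFrame:
    """Per-point change in curvature and orientation under a load step.

    Reference-configuration curves are fitted to the seeded positions and
    deformed-configuration curves to the displaced positions
    ``(x+u, y+v, z+w)`` against the same material arc length s, both
    weighted by the step's DVC residual.  Returns Δk = k_def − k_ref
    (µm⁻¹) and Δθ = θ_def − θ_ref wrapped to (−90°, 90°], joined with the
    reference metrics.
    """
    ref = compute_metrics(cloud, displacements=displacements, c_hat=c_hat)
    disp = displacements.set_index("n")
    moved = cloud.points.copy()
    matched = moved["n"].isin(disp.index[disp["converged"].astype(bool)])
    if not matched.all():
        logger.warning("dropping %d unmatched/non-converged points from delta metrics", int((~matched).sum()))
        moved = moved[matched.to_numpy()]
    uvw = disp.loc[moved["n"], ["u", "v", "w"]].to_numpy() * cloud.voxel_size
    moved = moved.copy()
    moved[["x", "y", "z"]] = moved[["x", "y", "z"]].to_numpy() + uvw
    def_cloud = FibrePointCloud(moved, cloud.spacing, cloud.voxel_size)
    dfm = compute_metrics(def_cloud, displacements=displacements, c_hat=c_hat)

    out = ref.merge(dfm[["n", "k", "theta"]], on="n", suffixes=("", "_def"))
    out["dk"] = out["k_def"] - out["k"]
    out["dtheta"] = wrap_angle_difference(out["theta_def"] - out["theta"])
    return out.reset_index(drop=True)
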