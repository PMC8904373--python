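# Methods

This note records the models implemented in `fibredvc`, the assumptions
behind them, the tunable parameters that matter, and the numerical and
design choices made where more than one reasonable option existed.

## Synthetic phantom

The phantom stands in for reconstructed tomograms of lamellar fibrous
tissue.  Lamellae are planar slabs stacked along **y** (the AF-depth
axis); within lamella *i* all fibres are parallel straight lines in the
x–z plane at angle `base_angles[i]` from the transverse (x–y) plane, on a
square lattice of pitch `fibre_spacing` (default 7 µm) in both cross-fibre
directions.  Each bundle has a Gaussian radial profile with FWHM =
2·`fibre_radius` (default 5 µm, the smallest feature a 1.625 µm/voxel scan
resolves) over a constant background at 20 % of core intensity.  Noiseless
intensities are min–max scaled into 16-bit (4,000–60,000, leaving
headroom for noise) and Gaussian grey-value noise of sd `noise_sd`
(default 3,000, i.e. fibre/background CNR ≈ 12, a plausible
no-phase-retrieval reconstruction) is added.

Real tissue makes axial motion observable through its native texture;
straight homogeneous cylinders would suffer the aperture problem.  The
phantom therefore modulates each fibre's intensity along its axis by
1 + a·clip(Σ wₘ sin(2π aᵢ/λₘ + φ), −1, 1) with amplitude a =
`axial_texture_amplitude` (default 0.4), wavelengths 5–21 voxels and
random per-fibre phases.  A texture-sufficiency test asserts that a
2-voxel axial shift of a sub-volume costs ≥ 10× the noise-floor ZNSSD.

What the phantom does **not** emulate: curved or doubly-curved lamellae
(fibres are straight, so reference curvature is zero — curvature accuracy
is instead validated on analytic circle/helix fixtures), incomplete
lamellae, intensity inhomogeneity, reconstruction artefacts (rings,
streaks), and spatially correlated noise.  Passing tests therefore
demonstrate correctness of the algorithms under known geometry and
additive white noise, not performance on artefact-laden scans.

Deformation fields are exact closed forms chosen so the inverse map is
also exact (triangular coordinate dependence): rigid translation; uniaxial
stretch/compression about the grid centre with an optional barrel-profile
lateral bulge; quadratic bending of the height coordinate; and rigid
translation plus a sinusoidal height ripple (the "known smooth sub-voxel
field" of the accuracy study).  Ground-truth fibre strain is
t·E t with E = (FᵀF − I)/2 from the analytic displacement gradient.
Warping uses the same interpolation contract as the correlator and
resamples under the exact inverse map, so warped volumes carry
machine-precision displacement truth; out-of-domain voxels are filled with
the background level and flagged.

## Sub-volume correlation

Translation-only (3-DOF) model: each fibre point is tracked as a rigid
translation of its spherical sub-volume (diameter 30 voxels ≈ 48 µm;
10,000 integer sample offsets drawn once, uniformly without replacement,
and shared by every point so residuals are comparable).  The objective is
the zero-normalised SSD of unit-normalised patches, reported as the
residual on the fixed scale 2·(1 − ZNCC) ∈ [0, 2]; it is invariant to
local intensity gain and offset.  Minimisation is damped Gauss–Newton with
the Jacobian from the analytic gradient of the interpolant; a step-norm
tolerance of 10⁻³ voxel declares convergence, objective increases back the
iterate off and raise the damping.

Processing order is (lamella, fibre, point); each point starts from the
previous converged solution on its fibre, else the nearest converged point
within two sub-volume diameters, else zero.  An optional exhaustive
integer pre-search (`coarse_search_radius_vox`, default off) exists for
load steps with multi-voxel bulk motion; it is deliberately not the
default because, at heavy noise, a blind pre-search can lock onto a
spurious along-fibre offset which the propagation then spreads along the
whole fibre.  Points whose sphere leaves the domain are flagged
out-of-domain and excluded from statistics; zero-variance patches are
flagged degenerate; neither is ever silently zeroed.

### Interpolation

Sub-voxel sampling uses an interpolating cubic **B-spline** (volumes are
prefiltered into spline coefficients; the basis is evaluated in compiled
code with analytic gradients).  Cubic convolution (Keys) was measured to
carry a systematic "S-curve" sub-voxel bias of ±0.05 voxel on the sharp
noisy phantom texture — enough to alias into a spurious +7 % strain error
under uniform stretch — whereas the B-spline basis reduces it to roughly
±0.03 and, combined with a mild Gaussian pre-smoothing of both volumes
(`presmooth_sigma_vox`, default 1.0 voxel, standard correlation practice),
to ±0.002 voxel.  The pre-smoothing barely widens the ~3-voxel fibre
profiles but suppresses the noise-driven component of the bias.

### Validation studies

*Tracking accuracy*: the default 256³ phantom is deformed by a rigid
(0.3, −0.2, 0.5)-voxel shift plus a 0.15-voxel sinusoidal ripple
(wavelength 120 voxels), resampled, given a fresh draw of the default
noise, and tracked at 2,000 uniformly random interior points.  Measured
mean 3D error ≈ 0.03 voxel (≈ 50 nm at 1.625 µm voxels).

*Strain uncertainty*: the phantom is correlated against copies of itself
with added Gaussian noise (true displacement and strain identically zero)
and the displacements pushed through the full metrics pipeline.  The
worst-case added level is the grey-value sd measured in the phantom's
structure-free background margin — the air-noise analogue of how such
studies are run on real scan series, where the measured scan noise is
added on top of the already-noisy first scan.  An alternative definition
(noise set for fibre/background CNR ≈ 2, i.e. ≈ 6× the scan's own noise)
was rejected: at that level the ZNSSD global minimum itself relocates by
~0.3–0.4 voxel along the fibre axis (confirmed by exhaustive search, so
it is not an optimiser failure), which contradicts the sub-0.2-voxel
accuracy regime the tracker is specified for.  At the adopted worst case
the strain sd is ≈ 1.3×10⁻⁴ and grows monotonically with noise; the
margin to the 6×10⁻⁴ qualification bound shrinks to ~2× at double that
noise.

Residual⁻¹ weighting of the curve fits is justified by a pooled study:
across runs at increasing noise, the Spearman correlation between a
point's ZNSSD residual and its true tracking error is ≈ +0.9.  Within a
single homogeneous-noise run the correlation can invert (sharp, strongly
textured regions have low residual but slightly larger resampling bias) —
a known limitation of per-point residual weighting.

## Space curves and fibre metrics

Per fibre, x, y and z are fitted independently against cumulative chord
arc length s with weighted cubic polynomials (weights 1/max(residual,
10⁻⁶); the floor stops perfect correlations from dominating).  Fitting
uses numpy's scaled polynomial domain for conditioning; coefficients are
converted back to raw-s form for storage.  Weighted per-axis R² values are
combined by variance weighting; the curve residual is the mean distance of
points from their fitted positions (voxels).

Derived per point: unit tangent t = f′/‖f′‖; curvature k = ‖f′×f″‖/‖f′‖³
(µm⁻¹); orientation θ from tan θ = |t×a|/(t·a) with a the tangent's
transverse-plane projection.  The raw angle lies in [0°, 90°]; to separate
the two criss-crossing fibre families each tangent is first flipped into
the half-space of a global circumferential direction ĉ (default +x), then
tangents rising out of the transverse plane keep the raw angle and falling
ones map to 180° − raw.  A rotation about the height axis therefore leaves
θ unchanged (it is an elevation), while a rotation about the lamella
normal shifts θ by exactly the rotation angle.  Tangents with in-plane
norm < 10⁻⁶ are defined as θ = 90°.  The displacement gradient m fits
u(s), v(s), w(s) the same way (displacements converted voxels → µm first,
so m is dimensionless), takes derivatives, and projects onto t; only
converged DVC points enter this fit, and fibres with fewer than four of
them get no strain.  L = m + m²/2.

Load-step changes (Δk, Δθ) refit the deformed configuration to the
displaced positions (x+u, y+v, z+w) against the same material arc length
s, with the current step's DVC residuals as weights; Δθ is wrapped to
(−90°, 90°] so changes near the family boundary report the smaller
equivalent rotation.  First and last points of every fibre are flagged
(polynomial derivatives are least constrained there) and excluded from
summary statistics, as are degenerate tangents.

Assumptions and limits: a single cubic per fibre is accurate for gently
curved fibres (circle-arc fixtures of ≤ 30° subtended angle fit to < 0.1 %
of radius); strongly kinked or long helical fibres exceed what one cubic
can follow, which shows up as low fit R².  Torsion is not computed.

## Tracing and seeding

Cylinder correlation scores each voxel with the best zero-normalised
correlation between its neighbourhood and a bright-core (radius 3 voxels)
/ suppressing-annulus (mask radius 5) cylinder of length 40 voxels over a
hemisphere of orientations (5° pitch ≈ 870 directions; antipodal
directions are equivalent).  An `erosion_vox` boundary shell (8, slightly
more than the template) is zeroed because the template correlates with
volume edges.  Tracing marches greedily from score maxima above
`min_start_score`, extending while the score exceeds
`min_continuation_score` and the direction turns < 30° per step; traced
voxels are suppressed within the marching-step radius so no two polylines
share a vertex.  The 0.5/0.4 defaults keep the 0.8 continuation/start
ratio of the reference tracing protocol, whose absolute score scale is
undocumented; parity with that commercial tracer is structural (counts,
coverage, orientation on phantoms), not numerical.  Traces do not
gap-close.  The stage is optional — centreline CSV ingestion produces the
identical downstream schema.

Seeding places points at exact arc-length multiples of the spacing
(default 8 µm) measured by cumulative chord length along the raw polyline;
the trailing remainder is dropped (no forced endpoint), keeping the s-grid
uniform for fitting.  Fibres yielding fewer than four points — the cubic
minimum — are excluded and logged.

## Statistics

Depth groups are tertiles of the lamella index with remainders assigned
outward-first (7 lamellae → 3/2/2).  Densities are Gaussian KDEs with
Silverman bandwidth floored at one grid step (orientation grid 0–180° at
0.25°; other metrics 512 data-driven steps); peaks are strict local maxima
above 10 % of the global maximum (suppressing noise peaks), sorted by
height.  Two-sample KS tests use the asymptotic p-value and are reported
raw — no multiple-testing correction — which the report states in its
output metadata.  Whether published peak tables derive from smoothed
densities or histogram modes is unknowable from their description; KDE was
chosen and is logged.

## Reproducibility and problem sizes

All randomness flows from explicit integer seeds; the pipeline fans a
single run seed out to per-stage seeds by fixed offsets, and a rerun with
the same config writes byte-identical CSVs.  Physical quantities are
carried in µm; voxel units appear only at volume boundaries
(0-based (x, y, z) indices, z the height/compression axis, position =
index × voxel size).

Study sizes are chosen for single-CPU desk runs: the accuracy and
strain-uncertainty studies use the default 256³ phantom with 2,000 random
points and a 50-fibre (~1,300-point) cloud respectively; unit tests use
64³–96³ phantoms, scaled cylinder templates, and coarser (15°) angular
sampling.  The quantities being validated are per-point, so these sizes
change statistical precision, not the measured accuracies themselves.
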