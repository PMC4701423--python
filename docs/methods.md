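# Methods

## Physical model and assumptions

A tracer (solute) of hydrodynamic radius *a* diffuses with free diffusivity
D_0 through a solution of polymer molecules of hydrodynamic radius *R* at
mass concentration *c*. The polymers are idealized as stationary,
impenetrable spheres on a simple-cubic lattice with center spacing
L = (M_W/(c N_A))^(1/3). Because the tracer center cannot approach a
polymer center closer than R + a, it diffuses in the complement of spheres
of radius R + a, and the problem depends only on ρ = 2(R + a)/L. The model
neglects polymer mobility (valid when the polymer is several-fold larger
than the solute), solute–polymer attraction or repulsion (obstruction
only), hydrodynamic interactions, polydispersity, and coil flexibility —
the last is why predictions are expected to over-estimate hindrance above
the overlap concentration, where real chains interpenetrate instead of
packing like hard spheres.

Two overlap thresholds bound the dilute/semi-dilute regime: the coil
overlap concentration c\* = M_W/((4/3)π R_g³ N_A) and the geometric overlap
concentration c^θ = M_W/(8 R_h³ N_A), at which the equivalent hard spheres
touch (ρ = 1 for a point tracer). N_A is fixed at 6.022×10²³ mol⁻¹ to
match the reference tables digit for digit.

For 1 < ρ < √2 the exclusion spheres overlap their six axis neighbours;
the obstructed fraction is computed by pairwise inclusion–exclusion
(φ = (4/3)πr³ − 6·πh²(3r−h)/3 with r = ρ/2, h = r − 1/2), which is exact
below ρ = √2 because no triple overlaps occur there. This closed form is
verified against a ≥4×10⁶-point Monte Carlo volume estimate in the tests.
At ρ = √2 the void space disconnects and every entry point raises a
disconnected-void error.

## Unit-cell solver

The corrector problem is solved in the flux form for u = x_j + ω_j, which
is periodic up to a unit jump across the cell in direction j; the obstacle
Neumann condition becomes a plain no-flux condition. A conservative
finite-volume scheme on a regular n³ grid assigns each face a
transmissibility equal to its open area fraction, estimated by 4×4
midpoint sub-sampling of the face against the exact sphere geometry
(`scheme="subcell"`, the default). Cell fluid volumes use matching 4³
sub-sampling so the quadrature is consistent with the stencil. A binary
variant (transmissibility 0/1 from a cell-center test) is retained for
comparison; it converges only O(h) with staircase oscillation and needs
roughly n > 500 to reach the accuracy the face-fraction scheme attains at
n = 64, which is why the face-fraction scheme is the default.

The discrete system is singular but consistent; it is solved with
Jacobi-preconditioned conjugate gradients to a relative residual of 1e-8
(iteration cap 50 000), and the corrector gauge is fixed afterwards by
zero mean over fluid cells. De/D0 is evaluated as the conserved flux
through any cross-section divided by the fluid volume — algebraically
identical to the face-quadrature of (1/|Ω̄|)∫(1 + ∂ω_j/∂x_j)dx. Because
the background gradient enters through the same face quadrature, an empty
cell returns exactly 1. Two conventions are reported: the fluid-average
De/D0 (appropriate when the tracer is excluded from the obstructions, as
in FCS of freshly mixed solutions) and De(1−φ)/D0 (appropriate when the
initial tracer distribution spans the whole volume).

Correctness anchors, independent of the sphere geometry: a transversely
invariant layered cell must return the exact harmonic mean of its face
fractions (series resistances), and a parallel-channel cell the arithmetic
mean. Physical anchors: the dilute expansion De/D0 → 1 − φ/2 + O(φ²), and
grid-refinement convergence |De(n) − De(1.5n)| ≤ 1e-3 at the default
resolutions (n = 64 for ρ ≤ 1.2, n = 128 beyond, where the void throat
narrows towards the ρ = √2 connectivity limit). Discrete connectivity is
checked by flood-filling a 2×2×2 tiling of the mask — a single wrapped
cell cannot distinguish a corner pocket touching its own image from a
genuine periodic channel.

The isotropy of the full tensor (equal diagonal, off-diagonals below 1e-3)
for the centered sphere is asserted rather than assumed; only one
corrector is solved when the scalar value is needed.

## Random-walk simulators

Both simulators run in units where D_0 = 1 and lengths are nanometres,
with lattice spacing L = 5 throughout — the most conservative (smallest)
spacing of the experimentally relevant range, making the scale separation
hardest rather than easiest. Obstruction queries are O(1): the nearest
sphere center is the nearest lattice point, and exact ray–sphere
intersection scans the 27 surrounding lattice images (exhaustive for
sub-segments shorter than 0.45 L). A free-flight shortcut skips the scan
whenever the nearest surface is farther than the remaining path.

**Reflected Wiener (Euler).** Gaussian increments of variance 2 D_0 dt per
axis; each increment is ray-traced, and wherever it crosses a sphere the
residual path length is reflected specularly about the surface normal,
iterated up to 1000 bounces. Exact ray tracing (rather than an
endpoint-inside test) means thin obstacles cannot be tunnelled through.
In the cusp between touching spheres (ρ ≥ 1) specular bounces can
accumulate without bound; when the cap is reached the remaining path —
geometrically negligible by then — is dropped and counted in
`n_reflection_failures`. The default time step makes the RMS sub-step one
tenth of the narrowest void gap (L(1−ρ) below touching, L(√2−ρ) above);
supplying a larger dt raises a configuration error. Halving dt is asserted
to leave De statistically unchanged.

**Kinetic (velocity-jump).** Step lengths ~ Exp(λ = 0.2, the mean free
path of water in water, an upper bound for a larger solute), durations
~ Exp(τ), isotropic directions, rectilinear motion with the same specular
reflection, and each step's duration consumed uniformly along its
(possibly reflected) polyline, so recording times falling inside a step
are interpolated at constant speed along the path. The unobstructed walk
has E[step²] = 2λ², giving a large-t MSD slope of 2λ²/τ; the default
τ = λ²/(3 D_0) therefore reproduces the free slope 6 D_0, which the tests
confirm (De → D_0 within the CI at ρ = 0). Halving λ is likewise asserted
to leave De unchanged.

Ensembles record squared displacements (optionally positions) at 250
equidistant times including t = 0; the default horizon t_max = (4L)²/6D_0
lets the RMS free displacement span four lattice cells, comfortably past
the ~2L scale where hindered-but-normal behaviour is established. Each
walk draws from its own substream (seeds spawned from a single
`SeedSequence`), so ensembles are exactly reproducible and a recorded-
position audit (no point strictly inside an obstruction) runs on every
ensemble. Start positions are either the cell body-center (equidistant
from the eight nearest obstacles, so early diffusion is collision-free) or
uniform over the void by rejection sampling.

## MSD analysis

MSD(t_j) is the ensemble mean of per-walk squared displacements; its
standard error is the per-time sample SD over √N. The effective
diffusivity is the least-squares slope of MSD versus t constrained through
the origin, divided by 6. The default fit uses the full recorded window,
matching how the simulated estimates are compared against the unit-cell
curve; a tail option (t ≥ t_max/2) is available because the early
free-diffusion transient biases the full-window slope slightly upward.
The 95% interval comes from per-walk slope statistics — each walk yields
its own through-origin slope, and the interval is mean ± 1.96 SD/√N (the
mean of per-walk slopes coincides with the ensemble slope because the
estimator is linear); below N = 30 the normal quantile is widened to the
t quantile with a warning, and a walk-resampling bootstrap is available
behind a flag.

The anomalous-diffusion diagnostic fits a continuous piecewise-linear
model to ln(MSD/t) versus ln t (natural logarithms): segment slopes are
α_i − 1 and intercepts ln C_i of MSD = C_i t^α_i. Interior knots are
chosen by SSE-minimizing grid search over quantile candidates with
continuity enforced; the number of segments is the caller's choice. For
the reflected Wiener walk the curve runs between the two plateaus
ln 6D_0 ≈ 1.79 and ln 6D_e, and the transition between them does not
follow a power law.

## Comparator models and the exponential law

fit_k minimizes the unweighted squared deviation of exp(−kρ³) from a
De/D0 curve over ρ ≤ 0.92 (a minimax variant is available; the two
criteria differ by well under the accepted tolerance on k). The reported
maximum absolute error is asserted to bound the pointwise residuals.
Maxwell's formula is implemented with general interior-to-exterior
diffusivity ratio δ (L_maxwell = 4π(1−δ)/(2+δ), named to avoid collision
with the lattice spacing); δ = 0 is the impenetrable case. Dividing by
1 − φ converts it from the whole-volume to the fluid-average convention.

## FCS module and the synthetic-curve generator

Only (N, τ_d) are fitted; the structure constant p is held fixed, as in
standard single-component practice. The beam waist default r_0 = 208 nm is
the documented calibration value; the axial ratio is not published, so
p defaults to 0.04 (a typical confocal geometry) and should be replaced by
the instrument's calibrated value — this default is a package choice, not
a measured constant. Initial guesses are N from 1/(G(τ_min) − 1) and τ_d
from the half-decay delay. Triplet and multi-component terms are omitted
(single-component fits suffice for the systems targeted).

The synthetic generator evaluates the model on a quasi-logarithmic delay
grid and adds i.i.d. zero-mean Gaussian noise. It emulates the shape and
amplitude of a correlator's output, not its physics: real FCS noise is
correlated across lags, lag-dependent, and accompanied by triplet
blinking, afterpulsing and photobleaching. Passing the recovery tests
therefore demonstrates that the fitter is accurate and nearly unbiased for
single-component decays with additive noise — it does not validate
robustness to those instrumental artifacts, and published goodness-of-fit
values for real measurements cannot be reproduced without the raw curves.

## Problem sizes and numerical tolerances

The test suite and the acceptance script use n = 64 for the sweep
(refinement-checked against n = 96 at the most obstructed point) and
Monte Carlo ensembles of N = 10⁴ walks, with CI widths extrapolated to the
reference ensemble size 10⁵ by 1/√N where a width at that size is quoted.
These sizes put every stochastic comparison several standard errors away
from its threshold while keeping a full run in minutes on one CPU. Paired
"invariance" checks (dt-halving, λ-halving) are asserted as statistical
indistinguishability at 95% of the two estimates.

Tie-breaks and degenerate inputs: a tangent (grazing) ray contact counts
as no collision (the zero-chord limit of oblique incidence); ρ = 0 runs
skip obstruction handling entirely; an all-zero MSD curve, a constant
observed vector in R², and curves shorter than the fit requires raise
errors rather than returning NaN.

## Known limitations

* The rigid-sphere geometry over-predicts hindrance in the concentrated
  regime (c > c^θ); `predict` flags such concentrations.
* Maxwell's rescaled formula tracks the unit-cell curve to ≤ 0.018 for
  ρ ≤ 0.92, but the deviation grows to 0.071 at sphere touching (ρ = 1) —
  the unit-cell value there (0.7211, grid-converged and confirmed
  independently by both random-walk models) reflects flux constriction
  that a dilute-limit formula cannot represent. A fixed 0.03 agreement
  band therefore fails on ρ ∈ [~0.95, 1].
* The printed reference table of (L, ρ) pairs reproduces exactly in L
  (one row excepted, presumed a typo) while its ρ column sits ~0.5% below
  2(R+a)/L for every row; the radii behind the printed ρ are not
  recoverable, so ρ is always recomputed from the definition.
* Random (non-lattice) obstacle placement, mobile obstacles, penetrable
  obstacles (δ > 0 beyond the Maxwell comparator), and fractional-
  diffusion model inference are out of scope.
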