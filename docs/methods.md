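# Methods

`esindy` implements ensemble sparse identification of nonlinear dynamics:
sparse regression of numerically estimated time derivatives onto a library
of candidate terms, robustified by bootstrap aggregating, with
inclusion-probability-based model selection, probabilistic forecasting,
uncertainty-driven active learning, and ensemble-model-based predictive
control. This note records the model assumptions, the numerical choices,
and what the synthetic studies do and do not demonstrate.

## Sparse model discovery

For an ODE system x' = f(x) observed at m times, the snapshot matrix
U ∈ R^{m×n} and its numerical time derivative U̇ are related through a
candidate library Θ(U) ∈ R^{m×D} by U̇ = Θ(U) Ξ with a sparse coefficient
matrix Ξ ∈ R^{D×n}. Libraries contain the constant, all multivariate
monomials up to a chosen total degree (graded lexicographic order, so term
indices are stable across runs — needed for comparing inclusion
probabilities), and optionally sin/cos of each state. For PDEs
u_t = N(u, u_x, …) the library columns are products u^a · ∂^d u/∂x^d over
all components on the grid, D = C(n+p, p) · (n·d_max + 1).

The solver is sequentially thresholded least squares / ridge regression:
iterate {ridge fit on the active columns; remove coefficients with
|ξ| < λ1; refit} until the support is stable, then refit the surviving
support by ordinary least squares. λ2 = 0 recovers plain STLS. Ties at
exactly λ1 are kept (removal uses strict inequality), so the procedure is
deterministic; the support can only shrink between iterations.

**Threshold normalization.** With `normalize_columns` on, both the library
columns and the regression target are scaled to unit ℓ2 norm during the
thresholding iterations, so λ1 acts as a *dimensionless contribution
threshold* (fraction of the target a column explains). This matters for
weak-form PDE systems whose targets and columns span many orders of
magnitude. Reported coefficients are always on the original scale. For
well-scaled ODE problems the default is plain absolute thresholding.

## Weak (integral) formulation

Pointwise PDE regression amplifies measurement noise by k^d when forming
spatial derivatives. The weak formulation instead multiplies the PDE by a
compactly supported test function w(x,t) = (1−x̄²)^{p_x} (1−t̄²)^{p_t} on a
rectangular subdomain (mapped to [−1,1]²) and integrates; K subdomains
give the linear system q0 = Q Ξ with q0_k = −∫∫ u ∂w/∂t (time derivative
always transferred). Per term:

- pure derivatives ∂^d u: all d integrations by parts transfer onto w
  (requires p_x ≥ d+1 for vanishing boundary terms; default p_x = d_max+2,
  p_t = 3);
- u^a u_x (first-order derivative of a pure power): conservative form
  −1/(a+1) ∫∫ u^{a+1} ∂w/∂x;
- remaining products: integrated directly, with the derivative factor
  computed spectrally from a *band-limited projection* of the field
  (lowest 15% of spatial modes by default). Without this projection the
  direct columns are 100–200× noise-dominated at 10% noise and recovery
  collapses; the retained band comfortably covers the benchmark signals'
  spectra, and clean-data bias is negligible (≤1e−4 relative on the
  Burgers benchmark).

Quadrature is the trapezoidal rule on the native grid (no interpolation);
the weak residual of a manufactured travelling wave converges at second
order under grid refinement. Subdomain centres are drawn uniformly without
replacement over admissible interior points (deterministic given the
seed); default half-widths are 10% of each extent and K = 1000 for the
benchmark (oversampled relative to D = 12, which is what gives the weak
form its noise averaging).

## Ensembles, inclusion probabilities, aggregation

- **Bagging**: q sparse fits on bootstrap resamples of the regression
  *rows* — (Θ row, target row) pairs are resampled jointly after library
  construction, so derivative stencils are never broken. Aggregate =
  elementwise mean of member coefficients (members with zero coefficients
  included in the mean).
- **Bragging**: median instead of mean; the aggregate is unchanged by
  corrupting any minority of members with arbitrarily large outliers.
- **Library bagging**: each member sees l of D columns drawn without
  replacement (optionally with a row bootstrap as well); members are
  zero-padded to the full library and the inclusion probability of a term
  is normalized by the number of members it was *offered* to, so rarely
  drawn terms are not biased low.

Inclusion probabilities (fraction of members with a nonzero coefficient)
drive selection twice: entries with inclusion below a threshold are zeroed
in the aggregate, and a large library can be *prescreened* by keeping only
terms whose max-over-states inclusion clears `keep_tol` before a second
ensemble pass. For library bagging the aggregate coefficients of the
selected support are refit by least squares on the full system when
`refit_aggregate` is set: the availability-weighted mean is biased by
members that were offered a term without its governing partners.

On clean chaotic data, members that were not offered a governing column
substitute correlated terms, so spurious inclusion under heavy
subsampling is *not* near zero (typically 0.3–0.7); selection relies on
the separation from the ≈1.0 inclusion of true terms, not on spurious
inclusion vanishing.

## Probabilistic forecasts

Ensemble forecasts draw `models_per_draw` members with replacement (5 by
default), average their coefficient matrices, and integrate from the
initial state (adaptive RK45, rtol 1e−8 / atol 1e−10); pointwise empirical
quantiles over 1000 such realizations form the predictive band. A state
excursion beyond |x| = 1e6 truncates that realization, which is excluded
from the quantiles and counted. Scoring uses the relative coefficient
error E_c = ‖Ξ_true − Ξ̂‖₂ / ‖Ξ_true‖₂ (Frobenius norm) and the success
rate, where a fit succeeds only if its nonzero/zero pattern matches the
truth exactly (a lenient per-term variant is available behind a flag).

## Synthetic systems and the noise model

Generators cover Lorenz (σ=10, ρ=28, β=8/3), Lotka–Volterra (a=1, b=0.1,
c=1.5, d=0.075 — artifact defaults with a conserved first integral used
as an oracle), inviscid Burgers (sine initial condition, integration
stopped before the shock), Korteweg–de Vries (the classical
interacting-soliton pair 3A² sech²(A(x−x₀)/2), A = 25 and 16, on [−π,π] —
the canonical discovery benchmark, integrated by ETDRK4), the focusing
nonlinear Schrödinger equation (split-step Fourier, complex field),
Kuramoto–Sivashinsky on L = 32π (ETDRK4, 50-time-unit spin-up onto the
chaotic attractor), and a two-component λ–ω reaction–diffusion system on
a periodic 1-D grid. Each system carries its ground-truth coefficient
matrix on a declared library, and every simulated field satisfies its own
governing equation in the weak sense (cross-module test).

Measurement noise is i.i.d. Gaussian with standard deviation equal to
`level` × the RMS amplitude of the clean signal, per component (complex
fields: circularly symmetric complex noise of that total standard
deviation). This convention is an artifact decision and is the knob for
all robustness studies.

## The noise-robustness benchmark

For Burgers and KdV, at each noise level and for each of 20 fresh noise
realizations, the weak system is assembled on freshly drawn subdomains
and fit two ways: the plain weak-form regression, and library bagging of
the weak system (q=100, l=D−2, member row bootstrap, high inclusion
threshold, refit aggregate). The per-system contribution thresholds are
λ1 = 0.1 (Burgers) and λ1 = 0.005 (KdV — at canonical soliton amplitudes
the dispersion term explains only ≈1.5% of u_t, so the threshold must sit
in the gap between it and the strongest spurious contribution, ≈0.08%).
Inclusion thresholds are 0.95 (Burgers) and 0.9 (KdV). The summary
statistic is the highest noise level at which the success rate stays at
or above 90% (linearly interpolated between tested levels); the headline
number is the ratio of the ensemble's level to the plain fit's. The
`desk` preset (two systems, 20 realizations per level) runs in about a
minute; the `full` preset covers all five PDEs at 100 realizations and is
a multi-hour run.

## The predator–prey pipeline

The bundled 21-sample yearly lynx–hare pelt record (the standard
published Hudson Bay counts, in thousands — the exact provenance file
varies between sources, so the table is a documented stand-in) is
rescaled to units of 10⁴ pelts and lightly smoothed with a smoothing
spline (penalty λ=0.1); the spline's derivative at the 21 sample years is
the regression target. A cubic polynomial library (D=10) is prescreened
by library bagging (q=300, l=8, row bootstrap, λ1=0.1, keep_tol=0.5),
which robustly isolates {1, hare, lynx, hare·lynx}; a bagging pass on the
reduced library (q=500, λ1=0.15) with the 65% inclusion threshold then
yields the Lotka–Volterra structure, with coefficients near the
literature values (growth ≈0.54/yr, predation ≈0.021 per thousand lynx).
The stage-2 ensemble is large (q=500) because two nuisance terms are
retained by ≈55–60% of bootstrap members — close enough to the 65%
threshold that a small ensemble's inclusion estimate can cross it by
sampling error alone. The plain thresholded fit, for comparison, stalls
on a dense 10-term model of this record at every threshold: the two-stage
ensemble route is what makes the 21-point problem solvable.

The 95% reconstruction band (5 models averaged per draw, 1000 draws)
covers ≈70% of the 42 observations. Full nominal coverage is not
achievable here: the record is not exactly Lotka–Volterra (its cycle
amplitude drifts), so a structural-mismatch residual remains whatever the
ensemble spread; the pipeline reports the measured coverage rather than
asserting calibration.

## Active learning

The loop: (1) fit an ensemble on a small budget of randomly initialized
short trajectory segments; (2) draw 200 candidate initial conditions
uniformly from the phase-space box and score each by the trace of the
member-terminal-state covariance after a single explicit-Euler step
(first-order stepping is deliberate — the score only *ranks* candidates);
(3) sample the true system at the arg-max candidate for one step, append,
refit. Acquired one-step segments enter the regression as a single
midpoint row (mean state paired with the interval slope): pairing an
endpoint state with the interval slope injects an O(Δt·f·∇f) bias that
otherwise surfaces as a spurious constant term. Longer segments are
differentiated after a Savitzky–Golay filter. The loop stops at the
iteration cap or when the member variance over the true-support
coefficients stays below tolerance for three consecutive iterations.
Study conditions: Lorenz at Δt=0.01, 0.5% RMS noise, initial budget 100
rows, 40 acquisitions, threshold λ1=0.5. The passive baseline is matched
in both budget and sample kind: the same initial segments plus the same
number of one-step acquisitions at *randomly* drawn initial conditions,
so the comparison isolates sample placement.

## Model predictive control

The plant is the Lorenz system with actuation added to the first state
equation; the goal is stabilizing the unstable spiral fixed point
(√72, √72, 27). Training records are sampled at Δt=0.05 (so 25/50/150
samples span 1.25–7.5 time units — at finer sampling the short records
cover too little of the state space for *any* regression to be
identifiable) under a slow three-tone multisine input (amplitude 25) with
1% RMS measurement noise. Models are quadratic in (x, y, z, u) with input
degree ≤ 1; the ensemble variant is a q=50 bragging ensemble at the 65%
inclusion threshold.

The controller solves, at each step, a single-shooting nonlinear program
over the next 10 inputs (quadratic state/input/input-rate costs, input
bounds ±50, model rolled out by fixed-step RK4 at Δt=0.01) with L-BFGS-B,
gradients by batched forward differences, warm-started from the shifted
previous solution; the first input is applied to the true plant.
Predicted states are clipped at ±10³ so a poorly identified model yields
large-but-finite costs instead of overflow. The reported J̄ is the mean
realized stage cost over a 200-step episode. Weights (state diag(1,1,1),
input 10⁻³, input-rate 10⁻³) and the horizon follow the standard
sparse-model MPC formulation and are artifact defaults.

## Scope of the synthetic evidence

All robustness and trend results are measured on the package's own
generators under the stated noise convention. They demonstrate the
mechanisms — bootstrap selection variability, inclusion-based pruning,
variance-targeted sampling — at desk scale (minutes on one core), with
sizes stated above. Real measurement records differ in ways the
generators do not emulate: correlated and non-Gaussian noise, unmeasured
states, non-uniform sampling, and model misspecification beyond the
library span. The lynx–hare pipeline is the one real-data study and
illustrates the last point: support recovery is robust, coefficient
values and band calibration inherit the structural mismatch.

## Known limitations

- One spatial dimension only; the reaction–diffusion case is handled as
  two coupled components on a single 1-D grid.
- The weak-form direct path relies on a fixed band-limit fraction; fields
  with genuinely broadband spectra would need it raised (at a noise cost).
- Exact-support success is brittle near threshold boundaries by
  construction; the per-term success variant is gentler but less
  interpretable.
- The MPC optimizer is a local quasi-Newton method; it can settle on the
  wrong lobe of the attractor for badly wrong models (this shows up as
  the failed low-data episodes, which is the phenomenon under study).
- Complex-field (Schrödinger) discovery uses a dedicated |u|^{2b}·∂^d u
  library and complex least squares; it is exercised by the generators
  and regression tests but not by the desk-scale benchmark preset.
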