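# Methods

## The model family

All computations concern two-species reaction-diffusion systems

    u_t = a_u Δu + f(u, v; β),
    v_t = a_v Δv + g(u, v; β),

on a square domain with no-flux (default) or periodic boundaries. Four
kinetic families are built in — Schnakenberg, FitzHugh–Nagumo, Brusselator
and Lengyel–Epstein (the CDIMA chemistry) — each in a dimensional form with
two diffusion coefficients and a non-dimensional form with a single
diffusion ratio `d`. The inverse problem is posed exclusively on the
non-dimensional forms: multiplying all parameters of a dimensional model by
a constant leaves a steady state a steady state, so a dimensional
parameterization is not identifiable from one stationary pattern.
Non-dimensionalization removes exactly that gauge freedom and shrinks the
parameter count.

The printed sources for the change-of-variables are unreliable, so each map
was re-derived symbolically and is accepted in the test suite only through
a behavioural contract: simulating the dimensional model and its
non-dimensional image from correspondingly scaled initial conditions must
give the same pattern after inverse scaling, to integrator accuracy. The
implemented maps are:

* Schnakenberg `(Du,Dv,c1,c2,c3,c4)`: concentration scale `a=sqrt(c2/c3)`,
  time `1/c2`, length `sqrt(Du/c2)`; non-dimensional parameters
  `(c1·sqrt(c3)/c2^{3/2}, 1, c4·sqrt(c3)/c2^{3/2}, Dv/Du)`, with `d` on the
  v-equation. The reference set `(1,40,0.1,1,1,0.9)` maps to
  `(0.1, 1, 0.9, 40)`.
* FitzHugh–Nagumo `(Du,Dv,c1,c2,c3)`: concentration scale `1/sqrt(c1)`,
  time `1/c1`, length `sqrt(Du/c1)`; parameters `(c2, c3/c1, 1/c1, Dv/Du)`,
  `d` on v. The reference set `(0.05, 0.00028, 10, 1, 1)` maps to
  `(1, 0.1, 0.1, 0.0056)`.
* Brusselator `(Du,Dv,c1,c2)`: scale `c1/(c2+1)`, time `1/(c2+1)`, length
  `sqrt(Dv/(c2+1))`; parameters `(c1²/(c2+1)³, c2/(c2+1), Du/Dv)`, `d` on u.

### Lengyel–Epstein kinetics

The package implements the canonical CDIMA kinetics

    f = c1 − u − 4 c2 · u v / (1 + u²),
    g =      u −   c2 · u v / (1 + u²),

i.e. the substrate-depletion term enters the activator equation with the
factor 4 and the inhibitor equation without it. A variant that carries the
factor 4 in **both** equations circulates in some transcriptions; linear
stability analysis shows that form admits no diffusion-driven instability
at all (both diagonal Jacobian entries are negative at its steady state,
so no diffusion ratio can destabilize it), so it cannot be the model behind
any observed CDIMA pattern and is not implemented. With the canonical form
the homogeneous steady state is `u* = c1/5`, `v* = (1 + u*²)/c2`. The model
is registered twice — variant `a` with the ratio `d` on Δu and variant `b`
with it on Δv — because with a single observed channel the placement of the
ratio is an empirical question (see "Single-channel workflow").

## Forward solver (synthetic-data generator)

Patterns are produced by the method of lines: 5-point Laplacian on an N×N
grid (default N=50, `dx=dy`), the resulting stiff 2N² ODE system integrated
with BDF using the analytic sparse Jacobian. Stepping is manual and the
L2 norm of the full time-derivative vector is checked at every accepted
step; integration stops once it falls below `tol` (default 1e-12, recorded
as "converged") or at `t_max` (default 5e5, the stop condition — not the
horizon — being the convergence authority; transients in these systems
persist to t ~ 1e5).

An optional cap on the number of accepted solver steps (stop reason
`max_steps`) bounds the cost of probing parameters far outside the Turing
region, where the stiff solver otherwise crawls with tiny steps;
re-simulation of inferred parameters uses a 50k-step budget by default.

No-flux boundaries use ghost cells mirrored about the cell face
(`u[-1] = u[0]`), the conservative Neumann discretization: with kinetics
switched off, total mass is preserved exactly, which the suite checks.

Initial conditions are the homogeneous steady state plus iid Gaussian pixel
noise with standard deviation `0.01 · max(|u*|, |v*|, 1)` by default. The
floor of 1 keeps models whose steady state sits at the origin
(FitzHugh–Nagumo) perturbable; the noise field is reproducible from the
stored seed and persists in every pattern's metadata.

The spatial step is a free choice because the study setup fixes only the
grid size; `dx` simply rescales `d` and the wavelength. Defaults are
chosen once per model so that roughly five to eight linear-instability
wavelengths fit the 50×50 grid (Schnakenberg 1.0, FitzHugh–Nagumo 0.25,
Brusselator non-dimensional 0.6, Lengyel–Epstein 0.2), giving the classic
spot/labyrinth morphologies. The Brusselator ships without a published
reference set; the documented example `(Du,Dv,c1,c2) = (1,10,2,3.4)` lies
inside the Turing region with ~8 wavelengths per 50-pixel grid.

A converged state counts as a "pattern" when `std(u) > 1e-3·|mean(u)| +
1e-6`. The absolute floor exists because a pure relative criterion is
meaningless for zero-mean steady states; 1e-6 sits many orders below any
real pattern amplitude and above integrator residue.

## Noise model and similarity measures

Relative noise of s% adds iid Gaussian noise with σ = (s/100)·Rp per
species, Rp = max − min of that species' grid. Patterns are compared by the
radially averaged power spectrum (RAPS): unnormalized 2D FFT power
(Parseval: Σ|F|² = N²Σ|grid|²), averaged over integer-radius annuli,
⌊N/2⌋+1 bins. The RAPS difference (RAPSD) is the mean squared difference
of two curves, DC bin excluded by default since it encodes only the mean
level; both choices are configurable. No windowing and no mean subtraction
are applied — range drift is itself diagnostic. Parameter accuracy is the
mean relative error `(1/p)Σ|β̂ᵢ−βᵢ|/|βᵢ|`; the undivided mean absolute
difference is available as a secondary statistic.

## Least-squares inverse solver

At steady state every non-dimensional model here is linear in its
parameters, so each pixel yields two linear equations (u- and v-equation)
with the parameter-multiplied terms — including `d` times the appropriate
finite-difference Laplacian — in the design matrix and everything else in
the response. The solve is a rank-revealing SVD (`lstsq`), not the normal
equations; the normal-equation route is retained purely as a cross-check
oracle. Rank deficiency warns and returns the minimum-norm solution.

Boundary pixels use the pattern's recorded boundary handling. Cropped
windows default to Laplacians computed from the uncropped neighbors (the
window pixels are assumed to carry correct local information); a
`laplacian_source="window"` mode recomputes them from the crop alone and
then uses only the window interior.

The minimum identifiable pixel count is found by drawing random pixel
subsets of growing size (up to 100 redraws per size — degenerate draws are
measure-zero) until the design reaches full column rank: 2 pixels for
Schnakenberg and Brusselator, 3 for FitzHugh–Nagumo (its two u-equation
rows only carry the c1 column and are collinear for any two pixels).

Noise and pixel-count experiments report mean relative error over ≥10
replicates. With noise, the error vs number of sampled pixels follows a
power law with exponent ≈ −1/2, the standard LS variance scaling
(each entry of XᵀX is a sum of N order-one products). Re-simulation of
inferred parameters reuses the original pattern's seed, spacing and
boundaries; forward failures (no admissible steady state, divergence) are
recorded as the homogeneous class rather than raised.

## RBF-PINN inverse solver

Each species is approximated by a radial-basis-function network
`Φ(x) = Σ wᵢ exp(−βᵢ‖x−cᵢ‖²)` whose Laplacian is closed-form:
`ΔΦ = Σ 4βᵢwᵢ e^{−βᵢr²}(βᵢr² − 1)`. Widths are stored as log βᵢ so
positivity is structural. Losses:

* approximation: MSE between network and observation, all pixels;
* PDE: mean squared steady-state residual with analytic network
  Laplacians, model parameters trainable, interior pixels only (default
  trim 3 → a 44×44 interior on the 50×50 grid);
* diffusion: MSE between the analytic network Laplacian and the 5-point
  finite-difference Laplacian of the data on the same interior. This
  anchors the network's second derivatives to the operator the data
  actually satisfies — the discretized pattern solves the *discrete*
  steady-state equation, and without this term the O(dx²) gap between the
  continuous and discrete Laplacians biases the parameter estimates. Its
  weight defaults to `diff_ratio = 5` times the PDE weight.

Training is Adam on hand-derived analytic gradients (every partial of the
Gaussian kernel is closed-form; the suite verifies all of them against
central differences). Two phases: a warmup (default 15k of 200k iterations,
minibatches of 128 pixels) minimizes the approximation losses only; then
the PDE and diffusion losses join with the PDE parameters marked trainable.
At the switch, and every 2000 iterations after, the PDE-loss weight is set
to L_app/L_PDE on the full interior so the terms stay on a common scale.
An alternative reading of periodic "re-weighting" — recycling kernels whose
weights have collapsed to a common scale — is available behind
`rebalance_mode="kernel"`.

Numerical choices that matter, with rationale:

* kernel centers uniform over the domain; weights Glorot-scale normal;
  widths centered on β₀ = 1/(2σ₀²) with σ₀ = λ_dom/4 from the dominant RAPS
  wavelength of the input, then jittered uniformly up to ×3 in either
  direction. The jitter gives the population both background-scale and
  feature-scale kernels, which measurably removes a bias in the constant
  production terms that a single-width population exhibits;
* learning rate 1e-3 for network parameters, 1e-2 for PDE (and scale)
  parameters — PDE constants travel distances O(10) (e.g. d: 1 → 40) while
  kernel parameters need fine steps — decaying geometrically to 5–10% of
  the initial value over the run to shrink the stochastic-gradient floor;
* PDE parameters initialize at 1.0; initializing at the LS estimate is
  available (`theta0="ls"`) but is not the default, so the two solvers stay
  independent;
* all randomness (init, batching) flows from one config seed; a fixed seed
  reproduces trajectories bit-for-bit.

The MLP-PINN baseline swaps in a tanh multilayer perceptron (default 5
hidden layers of 80 units, Glorot-initialized) under the identical loss
structure and schedule. Its input-Laplacian is the 5-point stencil of the
network at step `h = dx`, so its parameter gradients are stencil-weighted
standard backpropagations; matching the stencil to the data grid means a
perfect fit of noise-free data can, in principle, zero the PDE loss. The
RBF network uses ~4M parameters per species (M kernels × weight, log-width,
2D center) versus ~26k for the MLP.

There is no GPU tensor framework behind any of this: the networks, losses,
gradients and the Adam optimizer are explicit numpy, which for these sizes
(M ≈ 60–120, batches of 128) trains tens of thousands of iterations per
minute on one CPU core.

## Single-channel workflow

For an experimental image only one channel exists and its scale is
arbitrary. The image (or one channel of a synthetic pattern) is rescaled to
W ∈ [0, 1]; model concentrations are posited as linear maps
`u = κ_u W + γ_u`, `v = κ_v W + γ_v` (κ > 0 in phase, κ < 0 antiphase).
Two RBF subnetworks each approximate W; the scale maps are applied inside
the PDE loss, through which κ/γ can be co-trained. Training all four scale
parameters makes the problem underdetermined (γ_u plays the same role as
the basal production constant), so the default fixes the scale map — for
synthetic closed loops to the least-squares regression of the true
channels on W, for experimental data near a published set — and otherwise
pins γ_u while training the rest.

Variant selection: the diffusion ratio multiplies the Laplacian of the
*discarded* channel's approximation, which is reconstructed only through
the (imperfect) linear map, so using the wrong variant pushes inferred
constants out of the physical range. `select_variant` trains both variants
and keeps the one with all-non-negative constants (ties broken by PDE
residual); variant `a` winning identifies the observed channel as the
activator (iodide in CDIMA), variant `b` as the inhibitor.

Image import supports 8/16-bit grayscale PNG/TIFF, square crops, and area-
averaged resampling (preserves local mean intensity). Color images are
rejected unless conversion is requested; flat images raise a degenerate-
range error.

## Problem sizes used by the test suite and acceptance script

The suite runs every experiment at sizes a single CPU core handles in
minutes, as the package's own default study conditions: 50×50 grids
throughout; LS experiments at full scale (they are cheap); RBF-PINN
checks at 60–120 kernels and 30k–80k iterations (the CLI default remains
200k, the full-quality setting); noise-robustness at 8% relative noise
over 5 seeds; the chemical closed loop at a 40k-iteration budget.
Re-simulations for classification and RAPSD use a relaxed stationarity
tolerance (1e-6) since pattern morphology is settled long before the
1e-12 stationarity used for reference patterns.

## What the synthetic generator does and does not emulate

Synthetic patterns are exact steady states of the stated models corrupted
by pixel-iid Gaussian noise. Real micrographs add correlated noise, uneven
illumination, optical blur, boundary artefacts and — as in the CDIMA
dataset — possibly incomplete convergence of the pattern itself. Passing
tests therefore demonstrate correctness of the estimators under the stated
noise model, not performance on arbitrary experimental data; the
single-channel workflow's trim, free-scale and variant-selection machinery
is exactly the part that addresses (some of) that gap.

## Known limitations

* Steady-state only: growing domains and transient data are out of scope;
  model *discovery* (as opposed to parameter estimation for a named model)
  is not attempted.
* LS accuracy degrades quickly beyond ~0.5–1% relative noise; it is the
  fast, noise-free tool.
* RBF-PINN estimates carry a few-percent floor on noise-free data at
  moderate kernel counts (the approximation error of the network, not the
  optimizer, is limiting); more kernels and iterations shrink it.
* The free-scale problem is underdetermined with all scale parameters
  free; shift estimates can drift even when the recovered pattern is
  right.
* Two-species models only; no cross-diffusion.
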