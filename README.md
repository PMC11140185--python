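# turinverse

Forward simulation and single-snapshot parameter inference for stationary
Turing patterns.

## The problem

Reaction–diffusion systems of the activator–inhibitor type,

    u_t = a_u Δu + f(u, v; β),
    v_t = a_v Δv + g(u, v; β),

destabilize their homogeneous steady state when the inhibitor diffuses
sufficiently faster than the activator, producing stationary spots,
stripes and labyrinths. Linking an *observed* pattern back to the
parameters β of a candidate model — the inverse problem — is what it takes
to argue that a biological or chemical pattern really is a Turing pattern,
and to steer synthetic-biology circuits toward a desired one. It is hard
because patterns are noisy, initial conditions reshuffle the pattern
elements without changing the parameters, and a single stationary image is
often all the data there is.

`turinverse` is for computational biologists and pattern-formation
researchers who have exactly that: one (possibly noisy, possibly
single-channel) stationary pattern and a candidate model. It implements
two complementary estimators plus everything around them — the stiff
forward solver that doubles as synthetic-data generator, a relative-noise
model, spectral pattern-similarity measures, and a workflow for
experimental grayscale images of the CDIMA chemical reaction.

## The two estimators

**Steady-state least squares.** At steady state the non-dimensional models
are linear in β: each pixel (i,j), with finite-difference Laplacians, gives
two linear equations, collected into `y = Xβ` with one column per
parameter (the diffusion ratio d multiplies a Laplacian column). The
minimizer of `‖Xβ − y‖²` is computed by rank-revealing SVD. Noise-free,
this recovers parameters at numerical precision from as few as 2–3 pixels
(the rank of X decides identifiability: 2 pixels for Schnakenberg and
Brusselator, 3 for FitzHugh–Nagumo); with noise the error decays only as
N^(−1/2) in the number of pixels and the method breaks down around 0.5–1%
relative noise.

**RBF-PINN.** Each species is approximated by a radial-basis-function
network Φ(x) = Σᵢ wᵢ exp(−βᵢ‖x−cᵢ‖²), whose Laplacian is analytic. A
physics-informed loss — data misfit on all pixels, plus the squared
steady-state PDE residual and a second-derivative anchoring term on the
interior — is minimized with Adam in two phases (fit first, then co-train
the PDE parameters, loss weights rebalanced periodically). The network
smooths pixel noise by construction, which buys roughly an order of
magnitude more noise tolerance than least squares at correspondingly
higher compute cost. A conventional MLP-PINN baseline with the identical
loss structure is included for comparison.

Models built in (dimensional and non-dimensional): Schnakenberg,
FitzHugh–Nagumo, Brusselator, and both diffusion-placement variants of the
Lengyel–Epstein CDIMA model. See `docs/methods.md` for the equations,
non-dimensionalization maps, and every numerical choice.

## Worked example

```python
import numpy as np
from turinverse import (integrate_to_steady_state, build_design, solve_ls,
                        add_relative_noise, NoiseSpec, TrainConfig, train,
                        mean_relative_error)

beta = [0.1, 1.0, 0.9, 40.0]                      # (c1, c2, c3, d)
pattern = integrate_to_steady_state("schnakenberg_nd", beta, seed=1)
print(pattern.meta["stop"], pattern.meta["residual"])

res = solve_ls(build_design("schnakenberg_nd", pattern))
print("LS, noise-free:", mean_relative_error(res.beta_hat, beta))

noisy = add_relative_noise(pattern, NoiseSpec(s=1.0, seed=0))
res1 = solve_ls(build_design("schnakenberg_nd", noisy))
print("LS, 1% noise:  ", mean_relative_error(res1.beta_hat, beta))

cfg = TrainConfig(nodes=60, iters=30_000, warmup=10_000, seed=0)
noisy8 = add_relative_noise(pattern, NoiseSpec(s=8.0, seed=0))
_, res8 = train(noisy8, "schnakenberg_nd", cfg)
print("PINN, 8% noise:", np.round(res8.beta_hat, 2))
```

prints

```
converged 3.5764987467092184e-13
LS, noise-free: 3.3052264628944763e-15
LS, 1% noise:   0.7642251351016518
PINN, 8% noise: [ 0.23  0.89  0.94 25.64]
```

Read: the simulated spot pattern is stationary to ~1e-13; full-pixel least
squares returns the generating parameters to fifteen digits on clean data
but is off by ~78% on average at just 1% relative noise (those parameters
produce no pattern at all); the RBF-PINN at 8× that noise level still
lands in the Turing region — the re-simulated pattern has the same
morphology and wavelength as the original even though individual constants
(notably d) carry visible error.

The same API drives the cropped-window and random-pixel experiments
(`crop_experiment`, `random_pixel_sweep`), model mixing (`mix_models`),
and the single-channel chemical workflow (`free_scale`,
`infer_from_single_channel`, `select_variant`). A `turinverse` CLI wraps
the common paths (`simulate`, `noise`, `raps`, `infer-ls`, `infer-pinn`,
`infer-chem`, `sweep`); run any subcommand with `--help`.

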