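"""Steady-state least-squares inverse solver.

At steady state the non-dimensional model equations, evaluated pixel-wise
with finite-difference Laplacians, are *linear* in the parameter vector.
Each selected pixel therefore contributes two rows (the u- and v-equation)
to an overdetermined linear system ``X beta = y``, where every
parameter-multiplied term sits in a column of the design matrix X (the
diffusion ratio multiplies the appropriate Laplacian column) and all
parameter-free terms are moved to y.  The least-squares minimizer is
computed through a rank-revealing SVD factorization rather than the normal
equations ``(X^T X)^{-1} X^T y`` (identical minimizer, better conditioning);
the normal-equation route is kept as a cross-check oracle.

The module also hosts the LS experiments: cropped windows, random pixel
subsets with the N^{-1/2} error power law, the noise sweep with
re-simulation, and model mixing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import NoiseSpec, add_relative_noise, mean_relative_error, \
    pattern_raps, rapsd
from .models import KineticModel, NotNondimensionalError, \
    SteadyStateNotFoundError, _as_model
from .simulate import DivergenceError, IntegrationError, Pattern, \
    classify_pattern, integrate_to_steady_state, laplacian

__all__ = [
    "LSProblem",
    "InferenceResult",
    "IdentifiabilityError",
    "build_design",
    "solve_ls",
    "solve_normal_equations",
    "min_pixels",
    "crop_experiment",
    "random_pixel_sweep",
    "power_law_slope",
    "noise_sweep",
    "mix_models",
    "resimulate",
]


class IdentifiabilityError(RuntimeError):
    """The pixel set cannot give the design matrix full column rank."""


@dataclass
class LSProblem:
    X: np.ndarray
    y: np.ndarray
    pixels: list[tuple[int, int]]
    model: KineticModel

    def __post_init__(self):
        if self.X.shape[0] != 2 * len(self.pixels) or len(self.y) != self.X.shape[0]:
            raise ValueError("rows(X) must equal 2*|pixels| = len(y)")


@dataclass
class InferenceResult:
    beta_hat: np.ndarray
    residual_norm: float
    rank: int
    condition: float
    method: str = "ls"
    per_param_rel_err: np.ndarray | None = None
    extra: dict = field(default_factory=dict)

    def mean_rel_err(self, beta_true) -> float:
        return mean_relative_error(self.beta_hat, beta_true)


def build_design(model, pattern: Pattern, pixels=None) -> LSProblem:
    """Design matrix and response for the steady-state linear system.

    ``pixels`` is an ordered list of (row, col) indices; None selects every
    pixel.  Laplacians are taken on the full grid with the pattern's own
    boundary handling, so cropped/sub-sampled pixel sets still see correct
    neighbor information.
    """
    m = _as_model(model)
    if m.dimensional:
        raise NotNondimensionalError(
            f"LS design requires a non-dimensional model, got '{m.name}'")
    n = pattern.n
    if pixels is None:
        ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        pixels = list(zip(ii.ravel().tolist(), jj.ravel().tolist()))
    else:
        pixels = [(int(i), int(j)) for i, j in pixels]
        for i, j in pixels:
            if not (0 <= i < n and 0 <= j < n):
                raise IndexError(f"pixel ({i},{j}) outside {n}x{n} grid")
    lap_u = laplacian(pattern.u, pattern.dx, pattern.bc)
    lap_v = laplacian(pattern.v, pattern.dx, pattern.bc)
    A_u, b_u, A_v, b_v = m.linear_terms(pattern.u, pattern.v, lap_u, lap_v)
    rows = np.array([i for i, _ in pixels], dtype=int)
    cols = np.array([j for _, j in pixels], dtype=int)
    # two rows per pixel: u-equation then v-equation, grouped by equation
    Xu = A_u[:, rows, cols].T
    Xv = A_v[:, rows, cols].T
    X = np.concatenate([Xu, Xv], axis=0)
    y = -np.concatenate([b_u[rows, cols], b_v[rows, cols]])
    return LSProblem(X=X, y=y, pixels=pixels, model=m)


def solve_ls(problem: LSProblem) -> InferenceResult:
    """Least-squares solve via SVD; reports rank and condition number.

    On rank deficiency a warning is emitted and the minimum-norm solution
    is returned.
    """
    X, y = problem.X, problem.y
    if X.size == 0:
        raise ValueError("empty least-squares problem")
    p = X.shape[1]
    if X.shape[0] < p:
        raise IdentifiabilityError(
            f"{X.shape[0]} rows < {p} parameters: underdetermined system")
    beta, res, rank, sv = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        warnings.warn(
            f"design matrix rank {rank} < {p} parameters; "
            "returning minimum-norm solution", RuntimeWarning)
    cond = float(sv[0] / sv[rank - 1]) if rank > 0 else np.inf
    residual = float(np.linalg.norm(X @ beta - y))
    return InferenceResult(beta_hat=beta, residual_norm=residual,
                           rank=int(rank), condition=cond, method="ls")


def solve_normal_equations(problem: LSProblem) -> np.ndarray:
    """Textbook normal-equation solution (X^T X)^{-1} X^T y.

    Numerically inferior to :func:`solve_ls`; retained as an independent
    cross-check of the minimizer.
    """
    X, y = problem.X, problem.y
    return np.linalg.solve(X.T @ X, X.T @ y)


def min_pixels(model, pattern: Pattern, seed: int = 0,
               max_retries: int = 100, k_max: int | None = None) -> int:
    """Smallest number of randomly drawn pixels giving full column rank.

    Degenerate draws (a measure-zero event for generic pixel values) are
    resampled up to ``max_retries`` times per candidate count.
    """
    m = _as_model(model)
    p = m.n_params
    n = pattern.n
    if k_max is None:
        k_max = n * n
    rng = np.random.default_rng(seed)
    flat = np.arange(n * n)
    for k in range((p + 1) // 2, k_max + 1):
        for _ in range(max_retries):
            choice = rng.choice(flat, size=k, replace=False)
            pix = [(int(c // n), int(c % n)) for c in choice]
            prob = build_design(m, pattern, pix)
            if np.linalg.matrix_rank(prob.X) == p:
                return k
    raise IdentifiabilityError(
        f"no pixel subset up to size {k_max} reaches full rank for '{m.name}'")


def crop_experiment(model, pattern: Pattern, window,
                    laplacian_source: str = "full") -> InferenceResult:
    """LS restricted to a contiguous square window (i0, j0, size).

    With ``laplacian_source='full'`` (default) the Laplacians at window
    pixels use the true neighbors from the uncropped pattern; with
    ``'window'`` they are recomputed from the cropped sub-grid alone and
    only the window's interior pixels enter the system.
    """
    m = _as_model(model)
    i0, j0, size = (int(x) for x in window)
    n = pattern.n
    if size < 1 or i0 < 0 or j0 < 0 or i0 + size > n or j0 + size > n:
        raise IndexError(f"window {window} outside {n}x{n} grid")
    if laplacian_source == "full":
        pix = [(i, j) for i in range(i0, i0 + size) for j in range(j0, j0 + size)]
        if 2 * len(pix) < m.n_params:
            raise IdentifiabilityError(
                f"{len(pix)} pixels provide {2 * len(pix)} rows < "
                f"{m.n_params} parameters")
        return solve_ls(build_design(m, pattern, pix))
    if laplacian_source != "window":
        raise ValueError("laplacian_source must be 'full' or 'window'")
    sub = Pattern(pattern.u[i0:i0 + size, j0:j0 + size],
                  pattern.v[i0:i0 + size, j0:j0 + size],
                  pattern.dx, pattern.bc, dict(pattern.meta))
    inner = [(i, j) for i in range(1, size - 1) for j in range(1, size - 1)]
    if 2 * len(inner) < m.n_params:
        raise IdentifiabilityError(
            f"window interior has {len(inner)} pixels; need at least "
            f"{(m.n_params + 1) // 2}")
    return solve_ls(build_design(m, sub, inner))


def random_pixel_sweep(model, pattern: Pattern, ns, reps: int = 10,
                       spec: NoiseSpec | None = None,
                       seed: int = 0) -> pd.DataFrame:
    """Relative error of LS on random pixel subsets of increasing size.

    The pattern is corrupted once (if a noise spec is given); then for each
    subset size in ``ns``, ``reps`` independent uniform pixel draws are
    solved.  Returns a tidy table (n_pixels, rep, mean_rel_err, rank).
    """
    m = _as_model(model)
    beta_true = np.asarray(pattern.meta["beta"], float)
    work = add_relative_noise(pattern, spec) if spec and spec.s > 0 else pattern
    rng = np.random.default_rng(seed)
    n = pattern.n
    flat = np.arange(n * n)
    records = []
    for k in ns:
        k = int(k)
        for rep in range(int(reps)):
            choice = rng.choice(flat, size=k, replace=False)
            pix = [(int(c // n), int(c % n)) for c in choice]
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    res = solve_ls(build_design(m, work, pix))
                err = res.mean_rel_err(beta_true)
                rank = res.rank
            except (IdentifiabilityError, np.linalg.LinAlgError) as e:
                err, rank = np.nan, 0
            records.append({"n_pixels": k, "rep": rep,
                            "mean_rel_err": err, "rank": rank})
    return pd.DataFrame.from_records(records)


def power_law_slope(table: pd.DataFrame) -> float:
    """Log-log slope of mean relative error vs number of sampled pixels."""
    g = table.dropna().groupby("n_pixels")["mean_rel_err"].mean()
    if len(g) < 2:
        raise ValueError("need at least two subset sizes to fit a slope")
    slope = np.polyfit(np.log(g.index.to_numpy(float)),
                       np.log(g.to_numpy()), 1)[0]
    return float(slope)


def resimulate(model, beta_hat, reference: Pattern, tol: float = 1e-8,
               t_max: float = 1e5, max_steps: int = 50_000):
    """Re-run the forward solver with inferred parameters.

    Uses the reference pattern's own initial-condition seed, spacing and
    boundary handling so that patterns are directly comparable.  Returns
    (pattern | None, classification, rapsd_vs_reference); any failure of
    the forward problem (no steady state, divergence) is reported as the
    ``homogeneous`` class with NaN similarity rather than raised.  The
    solver-step cap bounds the cost of probing parameters far outside the
    Turing region, where the stiff solver can otherwise crawl.
    """
    meta = reference.meta
    try:
        sim = integrate_to_steady_state(
            model, np.asarray(beta_hat, float), n=reference.n,
            dx=reference.dx, bc=reference.bc, tol=tol, t_max=t_max,
            seed=int(meta.get("seed", 0)),
            amplitude=meta.get("amplitude"), max_steps=max_steps)
    except (SteadyStateNotFoundError, DivergenceError, IntegrationError):
        return None, "homogeneous", np.nan
    label = classify_pattern(sim)
    d = rapsd(pattern_raps(sim), pattern_raps(reference))
    return sim, label, d


def noise_sweep(model, pattern: Pattern, s_values, reps: int = 10,
                seed: int = 0, with_resimulation: bool = False,
                resim_tol: float = 1e-8,
                resim_t_max: float = 1e5) -> pd.DataFrame:
    """LS accuracy across relative-noise levels.

    For every noise level ``s`` (percent) and every replicate, the pattern
    is corrupted with a fresh noise realization and solved with all pixels.
    Optionally each estimate is pushed back through the forward solver to
    record the pattern/no-pattern classification and the RAPSD against the
    uncorrupted input.
    """
    m = _as_model(model)
    beta_true = np.asarray(pattern.meta["beta"], float)
    root = np.random.default_rng(seed)
    records = []
    for s in s_values:
        for rep in range(int(reps)):
            sub = int(root.integers(2 ** 31 - 1))
            noisy = add_relative_noise(pattern, NoiseSpec(s=float(s), seed=sub))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                res = solve_ls(build_design(m, noisy))
            rec = {"s": float(s), "rep": rep, "noise_seed": sub,
                   "mean_rel_err": res.mean_rel_err(beta_true),
                   "beta_hat": res.beta_hat.tolist()}
            if with_resimulation:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    _, label, d = resimulate(m, res.beta_hat, pattern,
                                             tol=resim_tol, t_max=resim_t_max)
                rec["classification"] = label
                rec["rapsd"] = d
            records.append(rec)
    return pd.DataFrame.from_records(records)


def mix_models(pattern_from_a: Pattern, design_model_b,
               with_resimulation: bool = True, resim_tol: float = 1e-8,
               resim_t_max: float = 1e5):
    """Solve a pattern from model A with model B's design ("mixing").

    Returns (InferenceResult, classification, rapsd).  When A == B this
    degenerates to ordinary recovery; across genuinely different models the
    estimate typically falls outside B's Turing region and re-simulation
    collapses to a homogeneous state.
    """
    m_b = _as_model(design_model_b)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = solve_ls(build_design(m_b, pattern_from_a))
    label, d = "unclassified", np.nan
    if with_resimulation:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            _, label, d = resimulate(m_b, res.beta_hat, pattern_from_a,
                                     tol=resim_tol, t_max=resim_t_max)
    res.extra["mixed_design"] = m_b.name
    res.extra["source_model"] = pattern_from_a.meta.get("model")
    return res, label, d
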