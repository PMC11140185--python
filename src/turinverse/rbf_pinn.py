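"""Physics-informed inverse solver built on radial-basis-function networks.

Each concentration field is approximated by a single-hidden-layer network of
M Gaussian bumps,

    Phi(x) = sum_i w_i * exp(-beta_i * ||x - c_i||^2),

whose spatial Laplacian is available in closed form,

    Lap Phi(x) = sum_i 4*beta_i*w_i * exp(-beta_i r_i^2) * (beta_i r_i^2 - 1).

Training jointly minimizes (i) an approximation loss, the MSE between the
network and the observed pattern over all pixels; (ii) a PDE loss, the mean
squared steady-state residual of the candidate model evaluated with the
network values and analytic network Laplacians on interior pixels, in which
the model parameters are themselves trainable; and (iii) a diffusion loss,
the MSE between the analytic network Laplacian and the finite-difference
Laplacian of the data, which anchors the second derivatives.  A two-phase
schedule first fits the pattern (approximation losses only), then switches
the PDE parameters on with the PDE/diffusion losses weighted onto the scale
of the approximation loss; the weight is re-balanced periodically.

All gradients are analytic and hand-derived (the Gaussian kernel makes every
partial closed-form); optimization is Adam.  A conventional
multilayer-perceptron PINN with tanh activations is provided as a baseline
with the identical loss structure; its input-Laplacian is taken by centered
finite differences of the network, so its weight gradients flow through
ordinary backpropagation at the five stencil points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .ls_inverse import InferenceResult, build_design, solve_ls
from .metrics import dominant_wavelength
from .models import NotNondimensionalError, _as_model
from .simulate import Pattern, laplacian

__all__ = [
    "RBFNet",
    "MLPNet",
    "TrainConfig",
    "Adam",
    "TrainingDivergedError",
    "rbf_eval",
    "rbf_laplacian",
    "losses",
    "interior_mask",
    "train",
    "mlp_pinn_baseline",
]


class TrainingDivergedError(RuntimeError):
    """Raised when a loss becomes non-finite; carries the last finite state."""

    def __init__(self, message, last_state=None):
        super().__init__(message)
        self.last_state = last_state


# ---------------------------------------------------------------------------
# networks


class RBFNet:
    """Gaussian-kernel network: centers (M,2), widths (log scale), weights.

    Widths are stored as log(beta_i) so positivity holds by construction.
    """

    def __init__(self, centers, log_widths, weights):
        self.centers = np.asarray(centers, float)
        self.log_widths = np.asarray(log_widths, float)
        self.weights = np.asarray(weights, float)
        m = self.centers.shape[0]
        if self.centers.shape != (m, 2) or self.log_widths.shape != (m,) \
                or self.weights.shape != (m,):
            raise ValueError("inconsistent RBF parameter shapes")

    @classmethod
    def init(cls, m: int, span: float, sigma0: float, rng,
             width_jitter: float = 3.0) -> "RBFNet":
        """Kernels uniform over [0, span]^2, Glorot-scale weights.

        Widths center on beta0 = 1/(2*sigma0^2), where sigma0 is set from
        the dominant pattern wavelength, and are jittered uniformly by up to
        a factor ``width_jitter`` either way so the population spans both
        background-scale and feature-scale kernels.
        """
        centers = rng.uniform(0.0, span, (m, 2))
        weights = rng.normal(0.0, np.sqrt(2.0 / (m + 1)), m)
        log_widths = np.full(m, np.log(1.0 / (2.0 * sigma0 ** 2)))
        if width_jitter > 1.0:
            log_widths = log_widths + rng.uniform(-np.log(width_jitter),
                                                  np.log(width_jitter), m)
        return cls(centers, log_widths, weights)

    @property
    def n_kernels(self) -> int:
        return self.centers.shape[0]

    @property
    def n_params(self) -> int:
        return 4 * self.n_kernels

    def params(self) -> dict[str, np.ndarray]:
        return {"centers": self.centers, "log_widths": self.log_widths,
                "weights": self.weights}

    # -- forward -----------------------------------------------------------

    def _cache(self, points):
        pts = np.atleast_2d(np.asarray(points, float))
        diff = pts[:, None, :] - self.centers[None, :, :]       # (B,M,2)
        r2 = np.einsum("bmk,bmk->bm", diff, diff)               # (B,M)
        beta = np.exp(self.log_widths)                          # (M,)
        s = r2 * beta[None, :]
        e = np.exp(-s)
        return diff, r2, beta, s, e

    def eval(self, points) -> np.ndarray:
        _, _, _, _, e = self._cache(points)
        return e @ self.weights

    def laplacian(self, points) -> np.ndarray:
        _, _, beta, s, e = self._cache(points)
        return (e * (s - 1.0)) @ (4.0 * beta * self.weights)

    def eval_lap(self, points):
        cache = self._cache(points)
        _, _, beta, s, e = cache
        phi = e @ self.weights
        lap = (e * (s - 1.0)) @ (4.0 * beta * self.weights)
        return phi, lap, cache

    # -- reverse mode --------------------------------------------------------

    def grads(self, cache, cot_val=None, cot_lap=None) -> dict[str, np.ndarray]:
        """Sum_b cot_val[b]*dPhi(x_b)/dp + cot_lap[b]*dLapPhi(x_b)/dp.

        All partials are closed-form derivatives of the Gaussian kernel.
        """
        diff, r2, beta, s, e = cache
        w = self.weights
        g_w = np.zeros_like(w)
        g_lb = np.zeros_like(w)
        g_c = np.zeros_like(self.centers)
        if cot_val is not None:
            cv = cot_val[:, None]
            g_w += (cv * e).sum(axis=0)
            # d/d(log beta) = beta * d/dbeta;  dPhi/dbeta_i = -w r^2 E
            g_lb += (cv * (-(w * beta)[None, :] * r2 * e)).sum(axis=0)
            # dPhi/dc_i = 2 w beta E (x - c)
            g_c += np.einsum("bm,bmk->mk", cv * (2.0 * (w * beta)[None, :] * e),
                             diff)
        if cot_lap is not None:
            cl = cot_lap[:, None]
            g_w += (cl * (4.0 * beta[None, :] * e * (s - 1.0))).sum(axis=0)
            # dLap/dbeta = 4 w E (3s - s^2 - 1);  chain to log beta
            g_lb += (cl * (4.0 * (w * beta)[None, :] * e
                           * (3.0 * s - s * s - 1.0))).sum(axis=0)
            # dLap/dc = -8 beta^2 w E (2 - s) (x - c)
            g_c += np.einsum(
                "bm,bmk->mk",
                cl * (-8.0 * (w * beta * beta)[None, :] * e * (2.0 - s)), diff)
        return {"centers": g_c, "log_widths": g_lb, "weights": g_w}


class MLPNet:
    """tanh multilayer perceptron (x, y) -> scalar, Glorot-initialized.

    The input-Laplacian is approximated by the 5-point centered stencil with
    step ``h``, so parameter gradients of the Laplacian are stencil-weighted
    backpropagations.
    """

    def __init__(self, weights: list[np.ndarray], biases: list[np.ndarray],
                 h: float = 0.5):
        self.weights_ = weights
        self.biases_ = biases
        self.h = float(h)

    @classmethod
    def init(cls, hidden: int = 80, depth: int = 5, h: float = 0.5,
             rng=None) -> "MLPNet":
        rng = rng or np.random.default_rng(0)
        dims = [2] + [hidden] * depth + [1]
        ws, bs = [], []
        for a, b in zip(dims[:-1], dims[1:]):
            ws.append(rng.normal(0.0, np.sqrt(2.0 / (a + b)), (a, b)))
            bs.append(np.zeros(b))
        return cls(ws, bs, h=h)

    @property
    def n_params(self) -> int:
        return sum(w.size for w in self.weights_) + sum(b.size for b in self.biases_)

    def params(self) -> dict[str, np.ndarray]:
        out = {}
        for k, (w, b) in enumerate(zip(self.weights_, self.biases_)):
            out[f"W{k}"] = w
            out[f"b{k}"] = b
        return out

    def _forward(self, pts):
        acts = [pts]
        a = pts
        nl = len(self.weights_)
        for k, (w, b) in enumerate(zip(self.weights_, self.biases_)):
            z = a @ w + b
            a = z if k == nl - 1 else np.tanh(z)
            acts.append(a)
        return a[:, 0], acts

    def eval(self, points) -> np.ndarray:
        return self._forward(np.atleast_2d(np.asarray(points, float)))[0]

    def _vjp(self, acts, cot):
        """Backprop a (B,) output cotangent; returns grads dict."""
        grads = {}
        delta = cot[:, None]                        # (B,1) at linear output
        nl = len(self.weights_)
        for k in range(nl - 1, -1, -1):
            a_prev = acts[k]
            grads[f"W{k}"] = a_prev.T @ delta
            grads[f"b{k}"] = delta.sum(axis=0)
            if k > 0:
                delta = (delta @ self.weights_[k].T) * (1.0 - acts[k] ** 2)
        return grads

    _STENCIL = ((0, 0, -4.0), (1, 0, 1.0), (-1, 0, 1.0), (0, 1, 1.0), (0, -1, 1.0))

    def eval_lap(self, points):
        pts = np.atleast_2d(np.asarray(points, float))
        caches = []
        vals = []
        for ox, oy, _c in self._STENCIL:
            shifted = pts + self.h * np.array([ox, oy])
            val, acts = self._forward(shifted)
            caches.append(acts)
            vals.append(val)
        phi = vals[0]
        lap = sum(c * v for (_, _, c), v in zip(self._STENCIL, vals)) / self.h ** 2
        return phi, lap, caches

    def grads(self, cache, cot_val=None, cot_lap=None) -> dict[str, np.ndarray]:
        total: dict[str, np.ndarray] = {}

        def acc(g):
            for k, v in g.items():
                total[k] = total.get(k, 0.0) + v

        if cot_val is not None:
            acc(self._vjp(cache[0], cot_val))
        if cot_lap is not None:
            for (_, _, c), acts in zip(self._STENCIL, cache):
                acc(self._vjp(acts, cot_lap * (c / self.h ** 2)))
        return total


# module-level conveniences mirroring the operation names

def rbf_eval(net: RBFNet, points) -> np.ndarray:
    return net.eval(points)


def rbf_laplacian(net: RBFNet, points) -> np.ndarray:
    return net.laplacian(points)


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    """Adam over a flat dict of named parameter arrays, with optional
    per-name learning-rate overrides."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 lr_overrides: dict[str, float] | None = None,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.lr_overrides = lr_overrides or {}
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray], only=None):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            if only is not None and k not in only:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            lr = self.lr_overrides.get(k, self.lr)
            self.params[k] -= lr * (self.m[k] / b1t) / \
                (np.sqrt(self.v[k] / b2t) + self.eps)


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class TrainConfig:
    """Hyper-parameters of the two-phase training schedule.

    ``nodes`` kernels per species network; minibatches of ``batch`` pixels;
    ``warmup`` approximation-only iterations out of ``iters`` total; losses
    re-balanced every ``rebalance_every`` iterations; PDE and diffusion
    losses restricted to pixels more than ``trim`` pixels from the boundary.
    ``lr_pde`` drives the PDE (and scale) parameters, which travel O(1-10)
    distances, faster than the network's fine-grained parameters.
    """

    nodes: int = 80
    batch: int = 128
    iters: int = 200_000
    warmup: int = 15_000
    rebalance_every: int = 2_000
    trim: int = 3
    lr: float = 1e-3
    lr_pde: float = 1e-2
    lr_final_frac: float = 0.05     # lr decays geometrically to this fraction
    w_pde: float | None = None      # None: auto-balanced against L_app
    w_diff: float | None = None     # None: diff_ratio * w_pde
    diff_ratio: float = 5.0         # diffusion-loss weight relative to PDE
    seed: int = 0
    rebalance_mode: str = "loss"    # "loss" | "kernel"
    log_every: int = 500
    theta0: np.ndarray | str | None = None  # None: ones; "ls": LS estimate

    def __post_init__(self):
        if not (0 <= self.warmup < self.iters):
            raise ValueError("need 0 <= warmup < iters")
        if not (1 <= self.trim <= 5):
            raise ValueError("trim must be in [1, 5]")
        if self.rebalance_mode not in ("loss", "kernel"):
            raise ValueError("rebalance_mode must be 'loss' or 'kernel'")


def interior_mask(n: int, trim: int) -> np.ndarray:
    """Boolean mask of pixels more than ``trim`` pixels from every edge."""
    m = np.zeros((n, n), dtype=bool)
    m[trim:n - trim, trim:n - trim] = True
    return m


# ---------------------------------------------------------------------------
# losses


def losses(net_u, net_v, pattern: Pattern, model, beta, trim: int = 3,
           scale=None):
    """(L_app_u, L_app_v, L_PDE, L_diff) on the full grid.

    Approximation losses use every pixel; PDE and diffusion losses only the
    interior (``trim`` pixels dropped at each edge).  ``scale`` maps network
    outputs to model concentrations (chem workflow); identity by default.
    """
    m = _as_model(model)
    if m.dimensional:
        raise NotNondimensionalError("PINN losses require a non-dimensional model")
    n = pattern.n
    pts = _grid_points(n, pattern.dx)
    tu, tv = _targets(pattern, scale)
    phi_u, lap_u, _ = net_u.eval_lap(pts)
    phi_v, lap_v, _ = net_v.eval_lap(pts)
    l_app_u = float(np.mean((phi_u - tu.ravel()) ** 2))
    l_app_v = float(np.mean((phi_v - tv.ravel()) ** 2))
    mask = interior_mask(n, trim).ravel()
    ku, gu, kv, gv = _scale_tuple(scale)
    ru, rv = m.residual(ku * phi_u[mask] + gu, kv * phi_v[mask] + gv,
                        ku * lap_u[mask], kv * lap_v[mask], beta)
    l_pde = float(np.mean(ru ** 2 + rv ** 2))
    fd_u = laplacian(tu, pattern.dx, pattern.bc).ravel()
    fd_v = laplacian(tv, pattern.dx, pattern.bc).ravel()
    l_diff = float(np.mean((lap_u[mask] - fd_u[mask]) ** 2
                           + (lap_v[mask] - fd_v[mask]) ** 2))
    return l_app_u, l_app_v, l_pde, l_diff


def _grid_points(n: int, dx: float) -> np.ndarray:
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    return np.column_stack([jj.ravel() * dx, ii.ravel() * dx]).astype(float)


def _scale_tuple(scale):
    if scale is None:
        return 1.0, 0.0, 1.0, 0.0
    return float(scale[0]), float(scale[1]), float(scale[2]), float(scale[3])


def _targets(pattern: Pattern, scale):
    """Observation grids each network is fitted to (u, v; or W, W)."""
    if scale is None or not getattr(pattern, "single_channel", False):
        return pattern.u, pattern.v
    return pattern.u, pattern.u


# ---------------------------------------------------------------------------
# training core (shared by the synthetic and the single-channel workflows)


def _training_loop(net_u, net_v, pattern: Pattern, model, config: TrainConfig,
                   scale=None, train_scales: tuple[bool, ...] = (False,) * 4,
                   theta0=None):
    m = _as_model(model)
    if m.dimensional:
        raise NotNondimensionalError("training requires a non-dimensional model")
    n = pattern.n
    dx = pattern.dx
    rng = np.random.default_rng(config.seed)
    pts_all = _grid_points(n, dx)
    tu, tv = _targets(pattern, scale)
    targ_u, targ_v = tu.ravel(), tv.ravel()
    fd_u = laplacian(tu, dx, pattern.bc).ravel()
    fd_v = laplacian(tv, dx, pattern.bc).ravel()
    mask = interior_mask(n, config.trim).ravel()
    interior_idx = np.flatnonzero(mask)

    theta = np.ones(m.n_params) if theta0 is None \
        else np.asarray(theta0, float).copy()
    sc = np.array(_scale_tuple(scale), float)
    sc_train = np.asarray(train_scales, bool)

    params: dict[str, np.ndarray] = {"theta": theta, "scale": sc}
    for pre, net in (("u_", net_u), ("v_", net_v)):
        for k, v in net.params().items():
            params[pre + k] = v
    lr_over = {"theta": config.lr_pde, "scale": config.lr_pde}
    opt = Adam(params, lr=config.lr, lr_overrides=lr_over)
    decay = config.lr_final_frac ** (1.0 / max(config.iters - 1, 1))
    net_names = [k for k in params if k.startswith(("u_", "v_"))]

    w_pde = config.w_pde
    w_diff = config.w_diff
    history = {k: [] for k in ("iteration", "l_app_u", "l_app_v", "l_pde",
                               "l_diff", "theta", "scale", "w_pde")}

    def full_losses():
        return losses(net_u, net_v, pattern, m, theta, trim=config.trim,
                      scale=sc if scale is not None else None)

    def rebalance():
        nonlocal w_pde, w_diff
        la_u, la_v, lp, ld = full_losses()
        if config.w_pde is None:
            w_pde = (la_u + la_v + 1e-12) / (lp + 1e-12)
        if config.w_diff is None:
            w_diff = config.diff_ratio * w_pde
        return la_u, la_v, lp, ld

    def recycle_kernels():
        # alternative reading of the periodic re-weighting: kernels whose
        # weights have collapsed are re-seeded at fresh positions with the
        # median width, keeping all kernel weights on a similar scale
        for pre, net in (("u_", net_u), ("v_", net_v)):
            if not isinstance(net, RBFNet):
                continue
            w = params[pre + "weights"]
            dead = np.abs(w) < 1e-3 * np.median(np.abs(w))
            if dead.any():
                k = int(dead.sum())
                params[pre + "centers"][dead] = rng.uniform(0, (n - 1) * dx, (k, 2))
                params[pre + "log_widths"][dead] = np.median(params[pre + "log_widths"])
                w[dead] = np.sign(rng.standard_normal(k)) * np.median(np.abs(w))

    last_state = None
    for it in range(config.iters):
        phase2 = it >= config.warmup
        if phase2 and (it == config.warmup or
                       (it - config.warmup) % config.rebalance_every == 0):
            if config.rebalance_mode == "loss" or it == config.warmup:
                rebalance()
            else:
                recycle_kernels()

        idx_app = rng.integers(0, n * n, config.batch)
        grads: dict[str, np.ndarray] = {}

        # approximation losses (all pixels eligible); value-only forward
        b_losses = {}
        pts_app = pts_all[idx_app]
        for pre, net, targ in (("u_", net_u, targ_u), ("v_", net_v, targ_v)):
            if isinstance(net, RBFNet):
                cache = net._cache(pts_app)
                phi = cache[4] @ net.weights
                r = phi - targ[idx_app]
                g = net.grads(cache, cot_val=(2.0 / config.batch) * r)
            else:
                phi, acts = net._forward(pts_app)
                r = phi - targ[idx_app]
                g = net._vjp(acts, (2.0 / config.batch) * r)
            b_losses["l_app_" + pre[0]] = float(np.mean(r * r))
            for k, v in g.items():
                grads[pre + k] = grads.get(pre + k, 0.0) + v

        b_losses["l_pde"] = np.nan
        b_losses["l_diff"] = np.nan
        if phase2:
            idx_pde = interior_idx[rng.integers(0, interior_idx.size, config.batch)]
            pts = pts_all[idx_pde]
            phi_u, lap_u, cache_u = net_u.eval_lap(pts)
            phi_v, lap_v, cache_v = net_v.eval_lap(pts)
            ku, gu, kv, gv = sc
            uu = ku * phi_u + gu
            vv = kv * phi_v + gv
            lu = ku * lap_u
            lv = kv * lap_v
            a_u, a_v = m.diffusion(theta)
            r_u = a_u * lu + m.f(uu, vv, theta)
            r_v = a_v * lv + m.g(uu, vv, theta)
            b_losses["l_pde"] = float(np.mean(r_u ** 2 + r_v ** 2))
            f_u, f_v, g_u, g_v = m.jacobian(uu, vv, theta)
            cu = (2.0 * w_pde / config.batch) * r_u
            cv = (2.0 * w_pde / config.batch) * r_v

            # theta gradient via the linear-in-parameters decomposition
            A_u, _, A_v, _ = m.linear_terms(uu, vv, lu, lv)
            grads["theta"] = grads.get("theta", 0.0) + A_u @ cu + A_v @ cv

            # scale gradients (chem workflow)
            if sc_train.any():
                g_sc = np.zeros(4)
                g_sc[0] = np.sum(cu * (a_u * lap_u + f_u * phi_u)
                                 + cv * (g_u * phi_u))
                g_sc[1] = np.sum(cu * f_u + cv * g_u)
                g_sc[2] = np.sum(cu * (f_v * phi_v)
                                 + cv * (a_v * lap_v + g_v * phi_v))
                g_sc[3] = np.sum(cu * f_v + cv * g_v)
                g_sc[~sc_train] = 0.0
                grads["scale"] = grads.get("scale", 0.0) + g_sc

            # network gradients through PDE residuals
            cot_u_val = cu * (f_u * ku) + cv * (g_u * ku)
            cot_u_lap = cu * (a_u * ku)
            cot_v_val = cu * (f_v * kv) + cv * (g_v * kv)
            cot_v_lap = cv * (a_v * kv)

            # diffusion loss: analytic net Laplacian vs FD data Laplacian
            r_du = lap_u - fd_u[idx_pde]
            r_dv = lap_v - fd_v[idx_pde]
            b_losses["l_diff"] = float(np.mean(r_du ** 2 + r_dv ** 2))
            cot_u_lap = cot_u_lap + (2.0 * w_diff / config.batch) * r_du
            cot_v_lap = cot_v_lap + (2.0 * w_diff / config.batch) * r_dv

            for pre, net, cache, cval, clap in (
                    ("u_", net_u, cache_u, cot_u_val, cot_u_lap),
                    ("v_", net_v, cache_v, cot_v_val, cot_v_lap)):
                g = net.grads(cache, cot_val=cval, cot_lap=clap)
                for k, v in g.items():
                    grads[pre + k] = grads.get(pre + k, 0.0) + v

        if not all(np.all(np.isfinite(np.atleast_1d(g)))
                   for g in grads.values()):
            raise TrainingDivergedError(
                f"non-finite gradient at iteration {it}", last_state)

        trainable = set(net_names)
        if phase2:
            trainable.add("theta")
            if sc_train.any():
                trainable.add("scale")
        opt.step(grads, only=trainable)
        opt.lr *= decay
        opt.lr_overrides = {k: v * decay for k, v in opt.lr_overrides.items()}

        if it % config.log_every == 0 or it == config.iters - 1:
            if any(not np.isfinite(v) for v in
                   (b_losses["l_app_u"], b_losses["l_app_v"])):
                raise TrainingDivergedError(
                    f"non-finite loss at iteration {it}", last_state)
            history["iteration"].append(it)
            history["l_app_u"].append(b_losses["l_app_u"])
            history["l_app_v"].append(b_losses["l_app_v"])
            history["l_pde"].append(b_losses["l_pde"])
            history["l_diff"].append(b_losses["l_diff"])
            history["theta"].append(theta.copy())
            history["scale"].append(sc.copy())
            history["w_pde"].append(w_pde if phase2 else np.nan)
            last_state = {k: v[-1] for k, v in history.items()}

    la_u, la_v, lp, ld = full_losses()
    result = InferenceResult(
        beta_hat=theta.copy(), residual_norm=float(np.sqrt(lp)),
        rank=m.n_params, condition=float("nan"), method="rbf_pinn",
        extra={"losses": {"l_app_u": la_u, "l_app_v": la_v,
                          "l_pde": lp, "l_diff": ld},
               "scale": sc.copy(), "net_u": net_u, "net_v": net_v})
    return history, result


def _init_theta(model, pattern, config: TrainConfig):
    m = _as_model(model)
    if config.theta0 is None:
        return np.ones(m.n_params)
    if isinstance(config.theta0, str):
        if config.theta0 != "ls":
            raise ValueError("theta0 must be None, 'ls' or an array")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return solve_ls(build_design(m, pattern)).beta_hat
    return np.asarray(config.theta0, float)


def train(pattern: Pattern, model, config: TrainConfig | None = None):
    """Two-phase RBF-PINN training on a two-channel pattern.

    Returns ``(history, InferenceResult)``; the history carries loss and
    parameter trajectories at ``log_every`` resolution, the result the final
    PDE parameter estimate and the trained networks.
    """
    config = config or TrainConfig()
    m = _as_model(model)
    rng = np.random.default_rng(config.seed)
    span = (pattern.n - 1) * pattern.dx
    sigma0 = dominant_wavelength(pattern.u, pattern.dx) / 4.0
    net_u = RBFNet.init(config.nodes, span, sigma0, rng)
    net_v = RBFNet.init(config.nodes, span, sigma0, rng)
    theta0 = _init_theta(m, pattern, config)
    return _training_loop(net_u, net_v, pattern, m, config, theta0=theta0)


def mlp_pinn_baseline(pattern: Pattern, model,
                      config: TrainConfig | None = None,
                      hidden: int = 80, depth: int = 5):
    """Vanilla MLP-PINN with the identical loss structure and schedule."""
    config = config or TrainConfig()
    m = _as_model(model)
    rng = np.random.default_rng(config.seed)
    net_u = MLPNet.init(hidden=hidden, depth=depth, h=pattern.dx, rng=rng)
    net_v = MLPNet.init(hidden=hidden, depth=depth, h=pattern.dx, rng=rng)
    theta0 = _init_theta(m, pattern, config)
    history, result = _training_loop(net_u, net_v, pattern, m, config,
                                     theta0=theta0)
    result.method = "mlp_pinn"
    return history, result
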