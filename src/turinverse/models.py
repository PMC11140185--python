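"""Reaction-diffusion model registry.

Two-species models of the form

    u_t = a_u * Lap(u) + f(u, v; beta)
    v_t = a_v * Lap(v) + g(u, v; beta)

are registered under string names, in dimensional form (independent diffusion
coefficients Du, Dv inside the parameter vector) and non-dimensional form
(a single diffusion ratio ``d`` on one of the two equations, the other fixed
at 1).  Non-dimensional kinetics are linear in the parameters, which is what
makes the steady-state least-squares inverse problem a linear one; each
non-dimensional model therefore also exposes its linear-in-parameters
decomposition of the steady-state residual.

Built-in models
---------------
``schnakenberg`` / ``schnakenberg_nd``
    f = c1 - c2*u + c3*u^2*v, g = c4 - c3*u^2*v (dimensional);
    f = c1 - u + c2*u^2*v,    g = c3 - c2*u^2*v (non-dimensional, d on v).
``fitzhugh_nagumo`` / ``fitzhugh_nagumo_nd``
    f = c1*(v - c2*u), g = -u + c3*v - v^3 (dimensional);
    f = v - c1*u,      g = c2*v - c3*u - v^3 (non-dimensional, d on v).
``brusselator`` / ``brusselator_nd``
    f = c1 - (c2+1)*u + u^2*v, g = c2*u - u^2*v (dimensional);
    f = 1 - u + c1*u^2*v,      g = c2*u - c1*u^2*v (non-dimensional, d on u).
``lengyel_epstein_a`` / ``lengyel_epstein_b``
    Non-dimensional CDIMA (chlorine dioxide-iodine-malonic acid) kinetics
    f = c1 - u - 4*c2*u*v/(1+u^2), g = u - c2*u*v/(1+u^2), with the
    diffusion ratio on the activator equation (variant ``a``) or on the
    inhibitor equation (variant ``b``).  The two variants describe the same
    chemistry under the two possible spatial rescalings; they differ in
    which Laplacian the trainable ratio multiplies, which matters when only
    one concentration channel is observed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "KineticModel",
    "VariableScaling",
    "MODEL_NAMES",
    "get_model",
    "evaluate_kinetics",
    "homogeneous_steady_state",
    "nondimensionalize",
    "UnknownModelError",
    "ParameterMismatchError",
    "SteadyStateNotFoundError",
    "InvalidParameterError",
    "NotNondimensionalError",
]


class UnknownModelError(KeyError):
    """Raised when a model name is not in the registry."""


class ParameterMismatchError(ValueError):
    """Raised when a parameter vector does not match the model layout."""


class SteadyStateNotFoundError(RuntimeError):
    """Raised when no admissible homogeneous steady state exists."""


class InvalidParameterError(ValueError):
    """Raised for physically inadmissible parameters (e.g. Du <= 0)."""


class NotNondimensionalError(ValueError):
    """Raised when an operation requires a non-dimensional model."""


@dataclass(frozen=True)
class VariableScaling:
    """Invertible map between dimensional and non-dimensional variables.

    Conventions: ``u_dim = conc * u_nd``, ``t_dim = time * t_nd``,
    ``x_dim = length * x_nd`` (same factor for u and v, and for x and y).
    """

    conc: float
    time: float
    length: float

    def to_nondim(self, grid: np.ndarray) -> np.ndarray:
        return np.asarray(grid) / self.conc

    def to_dim(self, grid: np.ndarray) -> np.ndarray:
        return np.asarray(grid) * self.conc


@dataclass(frozen=True)
class KineticModel:
    """A named two-species reaction-diffusion model.

    ``diffusion_on`` is ``'u'`` or ``'v'`` for non-dimensional models (the
    equation whose Laplacian carries the ratio ``d``); dimensional models
    carry ``Du``/``Dv`` inside the parameter vector instead.
    """

    name: str
    param_names: tuple[str, ...]
    dimensional: bool
    _f: Callable = field(repr=False)
    _g: Callable = field(repr=False)
    _jac: Callable = field(repr=False)
    _steady: Callable = field(repr=False)
    diffusion_on: str | None = None
    _linear_terms: Callable | None = field(default=None, repr=False)
    _nondim: Callable | None = field(default=None, repr=False)

    # -- parameter handling ------------------------------------------------

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def check_params(self, beta) -> np.ndarray:
        beta = np.asarray(beta, dtype=float)
        if beta.shape != (self.n_params,):
            raise ParameterMismatchError(
                f"model '{self.name}' expects {self.n_params} parameters "
                f"{self.param_names}, got shape {beta.shape}"
            )
        if not np.all(np.isfinite(beta)):
            raise ParameterMismatchError(
                f"non-finite parameter for model '{self.name}': {beta}"
            )
        return beta

    def params_as_dict(self, beta) -> dict[str, float]:
        beta = self.check_params(beta)
        return {n: float(b) for n, b in zip(self.param_names, beta)}

    def params_from_dict(self, d: dict) -> np.ndarray:
        try:
            return np.array([float(d[n]) for n in self.param_names])
        except KeyError as e:  # pragma: no cover - defensive
            raise ParameterMismatchError(
                f"missing parameter {e} for model '{self.name}'"
            ) from e

    # -- kinetics ----------------------------------------------------------

    def f(self, u, v, beta):
        return self._f(np.asarray(u), np.asarray(v), self.check_params(beta))

    def g(self, u, v, beta):
        return self._g(np.asarray(u), np.asarray(v), self.check_params(beta))

    def jacobian(self, u, v, beta):
        """Partial derivatives (f_u, f_v, g_u, g_v) of the kinetics."""
        return self._jac(np.asarray(u), np.asarray(v), self.check_params(beta))

    def diffusion(self, beta) -> tuple[float, float]:
        """Multipliers (a_u, a_v) of the two Laplacians."""
        beta = self.check_params(beta)
        if self.dimensional:
            p = self.params_as_dict(beta)
            return p["Du"], p["Dv"]
        d = beta[self.param_names.index("d")]
        return (d, 1.0) if self.diffusion_on == "u" else (1.0, d)

    # -- steady state ------------------------------------------------------

    def steady_state(self, beta) -> tuple[float, float]:
        beta = self.check_params(beta)
        uv = self._steady(beta)
        if uv is None or not np.all(np.isfinite(uv)):
            raise SteadyStateNotFoundError(
                f"no admissible homogeneous steady state for '{self.name}' "
                f"at {self.params_as_dict(beta)}"
            )
        u, v = float(uv[0]), float(uv[1])
        if abs(self._f(u, v, beta)) > 1e-10 or abs(self._g(u, v, beta)) > 1e-10:
            raise SteadyStateNotFoundError(
                f"steady-state residual above 1e-10 for '{self.name}'"
            )
        return u, v

    # -- linear-in-parameters decomposition (non-dimensional only) ---------

    def linear_terms(self, u, v, lap_u, lap_v):
        """Decompose the steady-state residuals linearly in the parameters.

        Returns ``(A_u, b_u, A_v, b_v)`` with ``A_*`` of shape
        ``(n_params,) + grid.shape`` such that

            R_u = sum_k beta_k * A_u[k] + b_u,
            R_v = sum_k beta_k * A_v[k] + b_v,

        where ``R_u = a_u*lap_u + f`` and ``R_v = a_v*lap_v + g`` are the
        steady-state residuals including diffusion.
        """
        if self._linear_terms is None:
            raise NotNondimensionalError(
                f"model '{self.name}' is dimensional; non-dimensionalize first"
            )
        u, v = np.asarray(u, float), np.asarray(v, float)
        return self._linear_terms(u, v, np.asarray(lap_u, float), np.asarray(lap_v, float))

    def residual(self, u, v, lap_u, lap_v, beta):
        """Steady-state residuals (R_u, R_v) including diffusion terms."""
        beta = self.check_params(beta)
        a_u, a_v = self.diffusion(beta)
        return (a_u * np.asarray(lap_u) + self.f(u, v, beta),
                a_v * np.asarray(lap_v) + self.g(u, v, beta))

    def nondimensionalize(self, beta):
        if self._nondim is None:
            raise NotNondimensionalError(
                f"model '{self.name}' is already non-dimensional"
            )
        return self._nondim(self.check_params(beta))


# ---------------------------------------------------------------------------
# helpers for registry definitions


def _stack(u, *terms):
    """Broadcast scalar/array terms against u and stack along axis 0."""
    shape = np.shape(u)
    out = np.empty((len(terms),) + shape, dtype=float)
    for k, t in enumerate(terms):
        out[k] = t
    return out


def _require_positive(names, values):
    for n, x in zip(names, values):
        if not x > 0:
            raise InvalidParameterError(f"parameter {n} must be positive, got {x}")


# ---------------------------------------------------------------------------
# Schnakenberg

def _schnak_nd_linear(u, v, lap_u, lap_v):
    uuv = u * u * v
    A_u = _stack(u, 1.0, uuv, 0.0, 0.0)
    b_u = lap_u - u
    A_v = _stack(u, 0.0, -uuv, 1.0, lap_v)
    b_v = np.zeros_like(b_u)
    return A_u, b_u, A_v, b_v


_SCHNAK_ND = KineticModel(
    name="schnakenberg_nd",
    param_names=("c1", "c2", "c3", "d"),
    dimensional=False,
    diffusion_on="v",
    _f=lambda u, v, b: b[0] - u + b[1] * u * u * v,
    _g=lambda u, v, b: b[2] - b[1] * u * u * v,
    _jac=lambda u, v, b: (-1.0 + 2 * b[1] * u * v, b[1] * u * u,
                          -2 * b[1] * u * v, -b[1] * u * u),
    _steady=lambda b: (b[0] + b[2], b[2] / (b[1] * (b[0] + b[2]) ** 2)),
    _linear_terms=_schnak_nd_linear,
)


def _schnak_nondim(beta):
    Du, Dv, c1, c2, c3, c4 = beta
    _require_positive(("Du", "Dv", "c2", "c3"), (Du, Dv, c2, c3))
    a = np.sqrt(c2 / c3)               # concentration scale: u = a*u_nd
    nd = np.array([c1 / (a * c2), c3 * a * a / c2, c4 / (a * c2), Dv / Du])
    scaling = VariableScaling(conc=a, time=1.0 / c2, length=np.sqrt(Du / c2))
    return _SCHNAK_ND, nd, scaling


_SCHNAK = KineticModel(
    name="schnakenberg",
    param_names=("Du", "Dv", "c1", "c2", "c3", "c4"),
    dimensional=True,
    _f=lambda u, v, b: b[2] - b[3] * u + b[4] * u * u * v,
    _g=lambda u, v, b: b[5] - b[4] * u * u * v,
    _jac=lambda u, v, b: (-b[3] + 2 * b[4] * u * v, b[4] * u * u,
                          -2 * b[4] * u * v, -b[4] * u * u),
    _steady=lambda b: ((b[2] + b[5]) / b[3],
                       b[5] * b[3] ** 2 / (b[4] * (b[2] + b[5]) ** 2)),
    _nondim=_schnak_nondim,
)


# ---------------------------------------------------------------------------
# FitzHugh-Nagumo
#
# The homogeneous steady state returned is the origin, which exists for every
# parameter set (additional non-zero roots appear when c2*c3 > c1*..., but the
# origin is the state perturbed in all simulations here).

def _fhn_nd_linear(u, v, lap_u, lap_v):
    A_u = _stack(u, -u, 0.0, 0.0, 0.0)
    b_u = lap_u + v
    A_v = _stack(u, 0.0, v, -u, lap_v)
    b_v = -(v ** 3)
    return A_u, b_u, A_v, b_v


_FHN_ND = KineticModel(
    name="fitzhugh_nagumo_nd",
    param_names=("c1", "c2", "c3", "d"),
    dimensional=False,
    diffusion_on="v",
    _f=lambda u, v, b: v - b[0] * u,
    _g=lambda u, v, b: b[1] * v - b[2] * u - v ** 3,
    _jac=lambda u, v, b: (np.broadcast_to(-b[0], np.shape(u)).astype(float),
                          np.broadcast_to(1.0, np.shape(u)),
                          np.broadcast_to(-b[2], np.shape(u)).astype(float),
                          b[1] - 3 * v * v),
    _steady=lambda b: (0.0, 0.0),
    _linear_terms=_fhn_nd_linear,
)


def _fhn_nondim(beta):
    Du, Dv, c1, c2, c3 = beta
    _require_positive(("Du", "Dv", "c1"), (Du, Dv, c1))
    nd = np.array([c2, c3 / c1, 1.0 / c1, Dv / Du])
    # u_nd = sqrt(c1) * u  =>  conc scale 1/sqrt(c1)
    scaling = VariableScaling(conc=1.0 / np.sqrt(c1), time=1.0 / c1,
                              length=np.sqrt(Du / c1))
    return _FHN_ND, nd, scaling


_FHN = KineticModel(
    name="fitzhugh_nagumo",
    param_names=("Du", "Dv", "c1", "c2", "c3"),
    dimensional=True,
    _f=lambda u, v, b: b[2] * (v - b[3] * u),
    _g=lambda u, v, b: -u + b[4] * v - v ** 3,
    _jac=lambda u, v, b: (np.broadcast_to(-b[2] * b[3], np.shape(u)).astype(float),
                          np.broadcast_to(b[2], np.shape(u)).astype(float),
                          np.broadcast_to(-1.0, np.shape(u)),
                          b[4] - 3 * v * v),
    _steady=lambda b: (0.0, 0.0),
    _nondim=_fhn_nondim,
)


# ---------------------------------------------------------------------------
# Brusselator

def _bruss_nd_linear(u, v, lap_u, lap_v):
    uuv = u * u * v
    A_u = _stack(u, uuv, 0.0, lap_u)
    b_u = 1.0 - u
    A_v = _stack(u, -uuv, u, 0.0)
    b_v = lap_v
    return A_u, b_u, A_v, b_v


def _bruss_nd_steady(b):
    c1, c2, _d = b
    if not 0 < c2 < 1:
        return None
    u = 1.0 / (1.0 - c2)
    return u, c2 / (c1 * u)


_BRUSS_ND = KineticModel(
    name="brusselator_nd",
    param_names=("c1", "c2", "d"),
    dimensional=False,
    diffusion_on="u",
    _f=lambda u, v, b: 1.0 - u + b[0] * u * u * v,
    _g=lambda u, v, b: b[1] * u - b[0] * u * u * v,
    _jac=lambda u, v, b: (-1.0 + 2 * b[0] * u * v, b[0] * u * u,
                          b[1] - 2 * b[0] * u * v, -b[0] * u * u),
    _steady=_bruss_nd_steady,
    _linear_terms=_bruss_nd_linear,
)


def _bruss_nondim(beta):
    Du, Dv, c1, c2 = beta
    _require_positive(("Du", "Dv", "c1", "c2"), (Du, Dv, c1, c2))
    tau = c2 + 1.0
    a = c1 / tau
    nd = np.array([c1 ** 2 / tau ** 3, c2 / tau, Du / Dv])
    scaling = VariableScaling(conc=a, time=1.0 / tau, length=np.sqrt(Dv / tau))
    return _BRUSS_ND, nd, scaling


_BRUSS = KineticModel(
    name="brusselator",
    param_names=("Du", "Dv", "c1", "c2"),
    dimensional=True,
    _f=lambda u, v, b: b[2] - (b[3] + 1.0) * u + u * u * v,
    _g=lambda u, v, b: b[3] * u - u * u * v,
    _jac=lambda u, v, b: (-(b[3] + 1.0) + 2 * u * v, u * u,
                          b[3] - 2 * u * v, -u * u),
    _steady=lambda b: (b[2], b[3] / b[2]),
    _nondim=_bruss_nondim,
)


# ---------------------------------------------------------------------------
# Lengyel-Epstein (non-dimensional CDIMA model, two diffusion placements)

def _le_f(u, v, b):
    return b[0] - u - 4.0 * b[1] * u * v / (1.0 + u * u)


def _le_g(u, v, b):
    return u - b[1] * u * v / (1.0 + u * u)


def _le_jac(u, v, b):
    den = 1.0 + u * u
    q_u = v * (1.0 - u * u) / den ** 2   # d(uv/(1+u^2))/du
    q_v = u / den
    return (-1.0 - 4.0 * b[1] * q_u, -4.0 * b[1] * q_v,
            1.0 - b[1] * q_u, -b[1] * q_v)


def _le_steady(b):
    if not b[1] > 0:
        return None
    u = b[0] / 5.0
    return u, (1.0 + u * u) / b[1]


def _le_linear(diffusion_on):
    def terms(u, v, lap_u, lap_v):
        den = 1.0 + u * u
        Q = 4.0 * u * v / den
        q = u * v / den
        if diffusion_on == "u":
            A_u = _stack(u, 1.0, -Q, lap_u)
            b_u = -u
            A_v = _stack(u, 0.0, -q, 0.0)
            b_v = lap_v + u
        else:
            A_u = _stack(u, 1.0, -Q, 0.0)
            b_u = lap_u - u
            A_v = _stack(u, 0.0, -q, lap_v)
            b_v = u + np.zeros_like(lap_v)
        return A_u, b_u, A_v, b_v
    return terms


_LE_A = KineticModel(
    name="lengyel_epstein_a",
    param_names=("c1", "c2", "d"),
    dimensional=False,
    diffusion_on="u",
    _f=_le_f, _g=_le_g, _jac=_le_jac, _steady=_le_steady,
    _linear_terms=_le_linear("u"),
)

_LE_B = KineticModel(
    name="lengyel_epstein_b",
    param_names=("c1", "c2", "d"),
    dimensional=False,
    diffusion_on="v",
    _f=_le_f, _g=_le_g, _jac=_le_jac, _steady=_le_steady,
    _linear_terms=_le_linear("v"),
)


# ---------------------------------------------------------------------------
# registry

_REGISTRY: dict[str, KineticModel] = {
    m.name: m
    for m in (_SCHNAK, _SCHNAK_ND, _FHN, _FHN_ND, _BRUSS, _BRUSS_ND, _LE_A, _LE_B)
}

MODEL_NAMES = tuple(sorted(_REGISTRY))


def get_model(name: str) -> KineticModel:
    """Look up a model by registry name."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise UnknownModelError(
            f"unknown model '{name}'; available: {', '.join(MODEL_NAMES)}"
        ) from None


# -- module-level functional API -------------------------------------------

def _as_model(model) -> KineticModel:
    return model if isinstance(model, KineticModel) else get_model(model)


def evaluate_kinetics(model, u, v, beta):
    """Element-wise reaction rates (f, g) for grids u, v."""
    m = _as_model(model)
    u, v = np.asarray(u, float), np.asarray(v, float)
    if u.shape != v.shape:
        raise ValueError(f"u and v shapes differ: {u.shape} vs {v.shape}")
    return m.f(u, v, beta), m.g(u, v, beta)


def homogeneous_steady_state(model, beta):
    """The spatially uniform state (u*, v*) with f = g = 0."""
    return _as_model(model).steady_state(beta)


def nondimensionalize(model, beta):
    """Map a dimensional model + parameters to (nd_model, nd_beta, scaling)."""
    return _as_model(model).nondimensionalize(beta)
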