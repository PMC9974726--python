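"""G-function families for cancer eco-evolutionary dynamics.

A fitness generating function ("G-function") maps a focal cell's heritable
strategy ``v``, the strategy vector ``u`` and density vector ``x`` of all
clones in the community, and time ``t`` to the focal cell's per-capita
growth rate.  Coupled with the canonical ecological and evolutionary
dynamics (see :mod:`gfuncsim.core`), a G-function fully specifies an
eco-evolutionary model.

Three families are provided:

``BasicGrowthModel``
    Logistic growth in which the carrying capacity is a Gaussian function
    of the strategy, maximised at ``v = 0``:
    ``G(v, x) = r (1 - x_total / K(v))`` with
    ``K(v) = K_m exp(-v^2 / (2 sigma_k2))``.

``CompetitionModel``
    Adds a Gaussian "like competes most with like" competition kernel
    ``a(v, u_i) = exp(-(v - u_i)^2 / (2 sigma_a2))`` so that
    ``G(v, u, x) = r (1 - sum_i a(v, u_i) x_i / K(v))``.  Each clone
    retains its own carrying capacity ``K(v)``.

``DrugResistanceModel``
    Logistic growth minus a density-independent, strategy-dependent kill
    rate ``s(v) = s_m exp(-(v - u_opt)^2 / (2 sigma_t2))`` applied from a
    treatment start time ``time_G`` onwards (a hard step; before onset the
    model is identical to basic growth).

All kernel functions are vectorised over ``v`` so the same code evaluates
single strategies and whole adaptive-landscape grids.
"""

from __future__ import annotations

import math
from abc import ABC, abstractmethod
from dataclasses import dataclass
from typing import ClassVar

import numpy as np

from .exceptions import ParameterDomainError, StructuralError

__all__ = [
    "BasicGrowthParams",
    "CompetitionParams",
    "DrugParams",
    "GFunctionModel",
    "BasicGrowthModel",
    "CompetitionModel",
    "DrugResistanceModel",
    "carrying_capacity",
    "competition_kernel",
    "kill_rate",
    "g_basic",
    "g_competition",
    "g_drug",
    "intrinsic_rate_from_doubling",
]


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not (value > 0) or not math.isfinite(value):
            raise ParameterDomainError(
                f"parameter {name!r} must be a positive finite number, got {value!r}"
            )


# ---------------------------------------------------------------------------
# Parameter bundles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BasicGrowthParams:
    """Parameters of the basic growth G-function.

    Attributes
    ----------
    r : float
        Intrinsic per-capita growth rate (1/time); equals ln(2)/D for a
        population with doubling time D under ample space and nutrients.
    K_m : float
        Absolute carrying capacity (cells), achieved at strategy v = 0.
    sigma_k2 : float
        Breadth (variance) of the Gaussian carrying-capacity function in
        squared strategy units.  Small values make K highly sensitive to
        deviations of the strategy from 0.
    """

    r: float
    K_m: float
    sigma_k2: float

    def __post_init__(self) -> None:
        _require_positive(r=self.r, K_m=self.K_m, sigma_k2=self.sigma_k2)


@dataclass(frozen=True)
class CompetitionParams:
    """Basic growth parameters plus the competition-kernel breadth.

    ``sigma_a2`` is the variance of the Gaussian competition kernel: the
    smaller it is, the more effectively clones with divergent strategies
    escape competition from one another (narrow niche).
    """

    base: BasicGrowthParams
    sigma_a2: float

    def __post_init__(self) -> None:
        _require_positive(sigma_a2=self.sigma_a2)


@dataclass(frozen=True)
class DrugParams:
    """Basic growth parameters plus the drug-kill term.

    Attributes
    ----------
    base : BasicGrowthParams
    s_m : float
        Maximal kill rate of the drug (1/time); s_m = 0 disables the drug.
    u_opt : float
        Strategy at which the drug is maximally effective.
    sigma_t2 : float
        Drug generality (variance of the Gaussian kill profile): how
        effective the drug remains as cells deviate from ``u_opt``.
    time_G : float
        Treatment start time; ``math.inf`` means treatment never starts.
        The kill term is a hard step: zero for t < time_G, full afterwards.
    """

    base: BasicGrowthParams
    s_m: float
    u_opt: float
    sigma_t2: float
    time_G: float = math.inf

    def __post_init__(self) -> None:
        if self.s_m < 0 or not math.isfinite(self.s_m):
            raise ParameterDomainError(f"s_m must be >= 0 and finite, got {self.s_m!r}")
        _require_positive(sigma_t2=self.sigma_t2)
        if not (self.time_G >= 0):  # NaN fails too
            raise ParameterDomainError(f"time_G must be >= 0 (inf allowed), got {self.time_G!r}")


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------

def carrying_capacity(v, K_m: float, sigma_k2: float):
    """Gaussian carrying capacity ``K(v) = K_m exp(-v^2 / (2 sigma_k2))``.

    Strictly positive, even in ``v``, maximised (``= K_m``) at ``v = 0``.
    """
    _require_positive(K_m=K_m, sigma_k2=sigma_k2)
    v = np.asarray(v, dtype=float)
    out = K_m * np.exp(-(v ** 2) / (2.0 * sigma_k2))
    return out if out.ndim else float(out)


def competition_kernel(v, u_i, sigma_a2: float):
    """Gaussian competition kernel ``a(v, u_i) = exp(-(v-u_i)^2 / (2 sigma_a2))``.

    Symmetric in its two strategy arguments, takes values in (0, 1], and
    equals 1 exactly when the focal strategy matches the competitor's
    ("like competes most with like").
    """
    _require_positive(sigma_a2=sigma_a2)
    v = np.asarray(v, dtype=float)
    u_i = np.asarray(u_i, dtype=float)
    out = np.exp(-((v - u_i) ** 2) / (2.0 * sigma_a2))
    return out if out.ndim else float(out)


def kill_rate(v, t: float, p: DrugParams):
    """Drug-induced per-capita death rate at time ``t``.

    Zero before treatment onset (``t < time_G``); afterwards a Gaussian in
    the strategy, peaking at ``s_m`` for ``v = u_opt``.
    """
    v = np.asarray(v, dtype=float)
    if t < p.time_G:
        out = np.zeros_like(v)
    else:
        out = p.s_m * np.exp(-((v - p.u_opt) ** 2) / (2.0 * p.sigma_t2))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# G-functions (free-function form)
# ---------------------------------------------------------------------------

def g_basic(v, x_total, p: BasicGrowthParams):
    """Per-capita growth rate ``r (1 - x_total / K(v))`` of the basic model."""
    v = np.asarray(v, dtype=float)
    K = p.K_m * np.exp(-(v ** 2) / (2.0 * p.sigma_k2))
    out = p.r * (1.0 - np.asarray(x_total, dtype=float) / K)
    return out if out.ndim else float(out)


def g_competition(v, u, x, p: CompetitionParams):
    """Per-capita growth rate with Gaussian intraspecific competition.

    ``G(v, u, x) = r (1 - sum_i a(v, u_i) x_i / K(v))``.  With a single
    clone at ``u_1 = v`` this reduces exactly to :func:`g_basic` because
    ``a(v, v) = 1``.
    """
    u = np.atleast_1d(np.asarray(u, dtype=float))
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if u.shape != x.shape:
        raise StructuralError(
            f"strategy vector u {u.shape} and density vector x {x.shape} differ in length"
        )
    v = np.asarray(v, dtype=float)
    vv = v[..., None]  # broadcast grid-of-v against clones
    a = np.exp(-((vv - u) ** 2) / (2.0 * p.sigma_a2))
    load = np.sum(a * x, axis=-1)
    K = p.base.K_m * np.exp(-(v ** 2) / (2.0 * p.base.sigma_k2))
    out = p.base.r * (1.0 - load / K)
    return out if out.ndim else float(out)


def g_drug(v, u, x, t: float, p: DrugParams):
    """Per-capita growth rate under therapy: ``r (1 - x_total/K(v)) - s(v, t)``.

    The community couples through total density only (the drug model has no
    strategy-dependent competition term), so multi-clone communities are
    well defined: all densities are summed.
    """
    x_total = float(np.sum(np.asarray(x, dtype=float)))
    base = g_basic(v, x_total, p.base)
    return base - kill_rate(v, t, p)


def intrinsic_rate_from_doubling(D: float) -> float:
    """Intrinsic growth rate r = ln(2)/D from a measured doubling time D."""
    if not (D > 0):
        raise ParameterDomainError(f"doubling time must be positive, got {D!r}")
    return math.log(2.0) / D


# ---------------------------------------------------------------------------
# Model classes (uniform interface used by the integrator)
# ---------------------------------------------------------------------------

class GFunctionModel(ABC):
    """Uniform interface over the three G-function families.

    ``g`` evaluates the fitness of a focal strategy ``v`` (scalar or grid)
    against a fixed community ``(u, x)`` at time ``t``; ``dg_dv`` is the
    closed-form fitness gradient with respect to ``v``.  Both hold the
    community fixed — the focal cell is vanishingly rare.
    """

    family: ClassVar[str]

    #: all built-in families supply a closed-form gradient
    has_analytic_gradient: ClassVar[bool] = True

    @abstractmethod
    def g(self, v, u, x, t: float = 0.0):
        """Per-capita growth rate of a focal cell with strategy ``v``."""

    @abstractmethod
    def dg_dv(self, v, u, x, t: float = 0.0):
        """Analytic fitness gradient dG/dv at ``v`` (community fixed)."""

    def d2g_dv2(self, v, u, x, t: float = 0.0, h: float = 1e-4) -> float:
        """Second strategy-derivative via central difference of ``dg_dv``."""
        step = h * max(1.0, abs(float(v)))
        return float(
            (self.dg_dv(v + step, u, x, t) - self.dg_dv(v - step, u, x, t)) / (2.0 * step)
        )

    def time_breakpoints(self) -> tuple[float, ...]:
        """Times at which the model's forcing is discontinuous in t."""
        return ()

    @abstractmethod
    def params_dict(self) -> dict:
        """Flat parameter mapping for serialization and run manifests."""


class BasicGrowthModel(GFunctionModel):
    """Logistic growth with Gaussian strategy-dependent carrying capacity."""

    family = "basic"

    def __init__(self, params: BasicGrowthParams):
        self.params = params

    def g(self, v, u, x, t: float = 0.0):
        return g_basic(v, float(np.sum(np.asarray(x, dtype=float))), self.params)

    def dg_dv(self, v, u, x, t: float = 0.0):
        # d/dv [ -r x / K(v) ] = -r x v exp(v^2/(2 s_k2)) / (K_m s_k2)
        p = self.params
        x_total = float(np.sum(np.asarray(x, dtype=float)))
        v = np.asarray(v, dtype=float)
        out = -p.r * x_total * v * np.exp(v ** 2 / (2.0 * p.sigma_k2)) / (p.K_m * p.sigma_k2)
        return out if out.ndim else float(out)

    def params_dict(self) -> dict:
        p = self.params
        return {"r": p.r, "K_m": p.K_m, "sigma_k2": p.sigma_k2}


class CompetitionModel(GFunctionModel):
    """Logistic growth with a Gaussian like-competes-most-with-like kernel."""

    family = "competition"

    def __init__(self, params: CompetitionParams):
        self.params = params

    def g(self, v, u, x, t: float = 0.0):
        return g_competition(v, u, x, self.params)

    def dg_dv(self, v, u, x, t: float = 0.0):
        p = self.params
        b = p.base
        u = np.atleast_1d(np.asarray(u, dtype=float))
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if u.shape != x.shape:
            raise StructuralError(
                f"strategy vector u {u.shape} and density vector x {x.shape} differ in length"
            )
        v = np.asarray(v, dtype=float)
        vv = v[..., None]
        a = np.exp(-((vv - u) ** 2) / (2.0 * p.sigma_a2))
        S = np.sum(a * x, axis=-1)
        dS = np.sum(a * x * (-(vv - u) / p.sigma_a2), axis=-1)
        K = b.K_m * np.exp(-(v ** 2) / (2.0 * b.sigma_k2))
        dK = -(v / b.sigma_k2) * K
        out = -b.r * (dS * K - S * dK) / K ** 2
        return out if out.ndim else float(out)

    def params_dict(self) -> dict:
        b = self.params.base
        return {"r": b.r, "K_m": b.K_m, "sigma_k2": b.sigma_k2, "sigma_a2": self.params.sigma_a2}


class DrugResistanceModel(GFunctionModel):
    """Logistic growth minus a strategy-targeted kill rate after onset."""

    family = "drug"

    def __init__(self, params: DrugParams):
        self.params = params

    def g(self, v, u, x, t: float = 0.0):
        return g_drug(v, u, x, t, self.params)

    def dg_dv(self, v, u, x, t: float = 0.0):
        p = self.params
        b = p.base
        x_total = float(np.sum(np.asarray(x, dtype=float)))
        v = np.asarray(v, dtype=float)
        grad = -b.r * x_total * v * np.exp(v ** 2 / (2.0 * b.sigma_k2)) / (b.K_m * b.sigma_k2)
        if t >= p.time_G and p.s_m > 0:
            s = p.s_m * np.exp(-((v - p.u_opt) ** 2) / (2.0 * p.sigma_t2))
            grad = grad + (v - p.u_opt) / p.sigma_t2 * s  # -ds/dv
        out = np.asarray(grad, dtype=float)
        return out if out.ndim else float(out)

    def time_breakpoints(self) -> tuple[float, ...]:
        return (self.params.time_G,) if math.isfinite(self.params.time_G) else ()

    def params_dict(self) -> dict:
        p = self.params
        b = p.base
        return {
            "r": b.r,
            "K_m": b.K_m,
            "sigma_k2": b.sigma_k2,
            "s_m": p.s_m,
            "u_opt": p.u_opt,
            "sigma_t2": p.sigma_t2,
            "time_G": p.time_G,
        }
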