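"""Eco-evolutionary equilibria: root finding, closed forms, ESS checks.

An eco-evolutionary equilibrium of an n-clone community is a joint root
of the 2n-dimensional system

    G(u_i, u, x) = 0        (ecological: every clone at zero growth)
    dG/dv|_{u_i} = 0        (evolutionary: every clone at a flat point)

A root where each resident sits on a local fitness *maximum* and no
strategy anywhere attains positive fitness satisfies the ESS maximum
principle: the resident community resists invasion by any rare mutant.
A root at a fitness *minimum* is convergent-stable at best but invadable
(the seed of evolutionary branching).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import root

from .core import CommunityState, eco_evo_rhs
from .landscape import default_grid
from .models import CompetitionParams, GFunctionModel

__all__ = [
    "EquilibriumResult",
    "MaxPrincipleReport",
    "solve_equilibrium",
    "dimorphic_ess_closed_form",
    "dimorphic_equilibrium",
    "verify_max_principle",
]

#: |d2G/dv2| below this is reported as degenerate rather than classified
DEGENERACY_TOL = 1e-8


@dataclass
class EquilibriumResult:
    """A candidate equilibrium with residuals and diagnostics.

    ``residual`` is the max-norm of the stacked system [G_i, dG/dv_i] at
    (u_star, x_star) — reported, never assumed zero.  ``classification``
    holds one flag per clone: ``fitness_maximum``, ``fitness_minimum`` or
    ``degenerate`` from the sign of the second strategy-derivative.
    """

    u_star: np.ndarray
    x_star: np.ndarray
    residual: float
    classification: list[str]
    converged: bool
    message: str = ""
    max_principle_ok: Optional[bool] = None
    diagnostics: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "u_star": self.u_star.tolist(),
                "x_star": self.x_star.tolist(),
                "residual": self.residual,
                "classification": self.classification,
                "converged": self.converged,
                "message": self.message,
                "max_principle_ok": self.max_principle_ok,
                "diagnostics": self.diagnostics,
            }
        )


def _stacked_residual(model: GFunctionModel, z: np.ndarray, n: int, t: float) -> np.ndarray:
    u, x = z[:n], z[n:]
    out = np.empty(2 * n)
    for i in range(n):
        out[i] = model.g(float(u[i]), u, x, t)
        out[n + i] = model.dg_dv(float(u[i]), u, x, t)
    return out


def _newton_pinv(fun, z0: np.ndarray, tol: float, max_iter: int = 60) -> tuple[np.ndarray, str]:
    """Damped Newton iteration using the pseudoinverse of an FD Jacobian.

    On rank-deficient systems (neutral directions, e.g. the density split
    between functionally identical competitors) the pseudoinverse gives
    the minimal-norm step, so iterates converge to the root *nearest* the
    guess instead of drifting along the neutral manifold.
    """
    def norm(f: np.ndarray) -> float:
        m = float(np.max(np.abs(f)))
        return m if math.isfinite(m) else math.inf

    z = z0.astype(float).copy()
    with np.errstate(all="ignore"):  # probe points may overflow the kernels
        f = fun(z)
        for _ in range(max_iter):
            if norm(f) < 0.01 * tol:
                break
            m = z.size
            J = np.empty((f.size, m))
            for j in range(m):
                h = 1e-7 * max(1.0, abs(z[j]))
                zp, zm = z.copy(), z.copy()
                zp[j] += h
                zm[j] -= h
                J[:, j] = (fun(zp) - fun(zm)) / (2.0 * h)
            if not np.all(np.isfinite(J)):
                break
            step, *_ = np.linalg.lstsq(J, -f, rcond=None)
            lam = 1.0
            improved = False
            for _ in range(40):
                z_new = z + lam * step
                f_new = fun(z_new)
                if norm(f_new) < norm(f):
                    improved = True
                    break
                lam *= 0.5
            if not improved:
                break
            z, f = z_new, f_new
    return z, "newton-pinv"


def solve_equilibrium(
    model: GFunctionModel,
    guess: CommunityState,
    t: float = 0.0,
    residual_tol: float = 1e-9,
) -> EquilibriumResult:
    """Solve {G_i = 0, dG/dv_i = 0} for (u*, x*) from the supplied guess.

    The morph count is fixed by the guess.  Multi-start: the guess itself
    plus its strategy-sign-flipped copy (to land on symmetric partners).
    Powell's hybrid method is tried first, then Levenberg-Marquardt, then
    a damped pseudoinverse Newton iteration that handles the
    rank-deficient cases (e.g. functionally identical competitors, where
    the density split is a neutral direction and the Jacobian is
    singular).
    """
    n = guess.n_clones
    z0 = np.concatenate([guess.u, guess.x])
    starts = [z0, np.concatenate([-guess.u, guess.x])]
    fun = lambda z: _stacked_residual(model, z, n, t)

    best_z, best_res, best_msg = z0, float(np.max(np.abs(fun(z0)))), "no solver attempt improved the guess"
    best_dist = 0.0
    found = False
    for start in starts:
        attempts = []
        for method in ("hybr", "lm"):
            try:
                sol = root(fun, start, method=method, tol=1e-13)
                attempts.append((sol.x.copy(), str(sol.message)))
            except Exception as exc:  # pragma: no cover - solver crash path
                attempts.append((start, f"{method} raised {exc!r}"))
        z_n, msg_n = _newton_pinv(fun, start, residual_tol)
        attempts.append((z_n, msg_n))
        for z_cand, msg in attempts:
            res = float(np.max(np.abs(fun(z_cand))))
            # prefer non-negative-density roots; penalise negative ones
            if np.any(z_cand[n:] < -1e-6):
                res = max(res, 1.0)
            dist = float(np.linalg.norm(z_cand - z0))
            ok = res < residual_tol
            # among converged roots pick the one nearest the original
            # guess (roots can form a continuum along neutral directions);
            # otherwise fall back to the smallest residual seen
            better = (ok and (not found or dist < best_dist)) or (not found and res < best_res)
            if better:
                best_z, best_res, best_msg, best_dist = z_cand.copy(), res, msg, dist
                found = found or ok
        if found:
            break

    u_star, x_star = best_z[:n], best_z[n:].copy()
    converged = best_res < residual_tol and bool(np.all(x_star > -1e-6))
    x_star = np.clip(x_star, 0.0, None)
    classification = []
    for i in range(n):
        d2 = model.d2g_dv2(float(u_star[i]), u_star, x_star, t)
        if abs(d2) < DEGENERACY_TOL:
            classification.append("degenerate")
        elif d2 < 0:
            classification.append("fitness_maximum")
        else:
            classification.append("fitness_minimum")
    result = EquilibriumResult(
        u_star=u_star,
        x_star=x_star,
        residual=best_res,
        classification=classification,
        converged=converged,
        message=best_msg if not converged else "converged",
        diagnostics={"residual_tol": residual_tol, "t": t},
    )
    if converged:
        report = verify_max_principle(model, result, t=t)
        result.max_principle_ok = report.ok
        result.diagnostics["max_principle"] = {
            "worst_v": report.worst_v,
            "worst_G": report.worst_G,
        }
    return result


def dimorphic_ess_closed_form(p: CompetitionParams) -> Optional[float]:
    """Strategy magnitude of the symmetric two-clone equilibrium, if any.

    At a symmetric dimorphism u* = (+d, -d) with equal densities, setting
    G = 0 and dG/dv = 0 and eliminating the density gives

        exp(-2 d^2 / sigma_a2) = sigma_a2 / (2 sigma_k2 - sigma_a2)

    hence  d = sqrt( (sigma_a2 / 2) * ln((2 sigma_k2 - sigma_a2) / sigma_a2) ).

    An interior root (d > 0) requires the log argument to exceed 1, i.e.
    sigma_a2 < sigma_k2 (niche narrow relative to the carrying-capacity
    breadth).  Otherwise None is returned: the only symmetric equilibrium
    is monomorphic at v = 0 with the clones splitting K_m evenly.
    """
    sa2, sk2 = p.sigma_a2, p.base.sigma_k2
    if sa2 >= sk2:
        return None
    return math.sqrt((sa2 / 2.0) * math.log((2.0 * sk2 - sa2) / sa2))


def dimorphic_equilibrium(p: CompetitionParams) -> Optional[tuple[float, float]]:
    """(strategy magnitude, per-clone density) of the symmetric dimorphism.

    The per-clone density follows from G = 0 at the equilibrium:
    x* = K(u*) / (1 + exp(-2 u*^2 / sigma_a2)); the total sits below K_m
    because both clones remain displaced from the carrying-capacity peak.
    """
    d = dimorphic_ess_closed_form(p)
    if d is None:
        return None
    b = p.base
    K = b.K_m * math.exp(-(d ** 2) / (2.0 * b.sigma_k2))
    x_each = K / (1.0 + math.exp(-2.0 * d ** 2 / p.sigma_a2))
    return d, x_each


@dataclass(frozen=True)
class MaxPrincipleReport:
    ok: bool
    worst_v: float
    worst_G: float


def verify_max_principle(
    model: GFunctionModel,
    eq: EquilibriumResult,
    v_grid: Optional[np.ndarray] = None,
    t: float = 0.0,
    tol: float = 1e-7,
) -> MaxPrincipleReport:
    """ESS check: no strategy on the grid attains fitness above ``tol``.

    Returns the grid argmax of G as the worst offender; a positive worst_G
    means the equilibrium is invadable (convergent-stable at best, not an
    ESS).
    """
    if v_grid is None:
        v_grid = default_grid()
    g = np.asarray(model.g(np.asarray(v_grid, dtype=float), eq.u_star, eq.x_star, t), dtype=float)
    j = int(np.argmax(g))
    ok = bool(g[j] <= tol)
    # residents must themselves sit at ~zero fitness
    for ui in eq.u_star:
        if abs(float(model.g(float(ui), eq.u_star, eq.x_star, t))) > tol:
            ok = False
    return MaxPrincipleReport(ok=ok, worst_v=float(v_grid[j]), worst_G=float(g[j]))


def equilibrium_rhs_norm(model: GFunctionModel, eq: EquilibriumResult, k: float = 0.2, t: float = 0.0) -> float:
    """Max-norm of the dynamical RHS at the equilibrium (consistency check)."""
    community = CommunityState.from_arrays(eq.u_star, eq.x_star, np.full_like(eq.u_star, k), t)
    dx, du = eco_evo_rhs(model, community, t)
    return float(max(np.max(np.abs(dx)), np.max(np.abs(du))))
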