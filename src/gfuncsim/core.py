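"""Coupled ecological/evolutionary dynamics for any G-function.

The state of a community of n clones is the pair of vectors (u, x):
heritable strategies and population densities.  Dynamics follow the
canonical pair of ordinary differential equations

    dx_i/dt = x_i * G(v, u, x, t) |_{v = u_i}          (ecology)
    du_i/dt = k_i * dG/dv |_{v = u_i}                  (evolution)

where k_i is the trait's evolvability: the constant converting the local
fitness gradient (the slope of the adaptive landscape at the clone's own
strategy) into a rate of strategy change.

Integration uses an adaptive high-order Runge-Kutta scheme
(scipy's DOP853).  Models whose forcing is discontinuous in time (the
drug model's treatment onset) advertise their breakpoints and the
integration is split there, so the solver never steps across the
discontinuity.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .exceptions import CapabilityError, NumericalDomainError, StructuralError
from .models import GFunctionModel

__all__ = [
    "CloneState",
    "CommunityState",
    "SimulationSpec",
    "Trajectory",
    "fitness_gradient",
    "eco_evo_rhs",
    "simulate",
    "run_to_stationarity",
]

logger = logging.getLogger("gfuncsim")

_FD_STEP = 1e-6  # relative central-difference step for gradient fallback


@dataclass
class CloneState:
    """One clone: strategy ``u``, density ``x``, evolvability ``k``."""

    u: float
    x: float
    k: float

    def __post_init__(self) -> None:
        if self.x < 0:
            raise StructuralError(f"clone density must be non-negative, got {self.x!r}")
        if self.k < 0:
            raise StructuralError(f"evolvability must be non-negative, got {self.k!r}")


@dataclass
class CommunityState:
    """Ordered collection of clones plus the current time.

    Clone order is stable: index i refers to the same lineage throughout a
    run.
    """

    clones: list[CloneState]
    t: float = 0.0

    def __post_init__(self) -> None:
        if len(self.clones) == 0:
            raise StructuralError("a community must contain at least one clone")

    @classmethod
    def from_arrays(cls, u, x, k, t: float = 0.0) -> "CommunityState":
        u, x, k = (np.atleast_1d(np.asarray(a, dtype=float)) for a in (u, x, k))
        if not (u.shape == x.shape == k.shape):
            raise StructuralError("u, x, k must have equal lengths")
        return cls([CloneState(float(ui), float(xi), float(ki)) for ui, xi, ki in zip(u, x, k)], t)

    @property
    def n_clones(self) -> int:
        return len(self.clones)

    @property
    def u(self) -> np.ndarray:
        return np.array([c.u for c in self.clones])

    @property
    def x(self) -> np.ndarray:
        return np.array([c.x for c in self.clones])

    @property
    def k(self) -> np.ndarray:
        return np.array([c.k for c in self.clones])


@dataclass
class SimulationSpec:
    """Integration settings.

    Parameters
    ----------
    t_end : float
        Horizon in (continuous) time steps.
    rel_tol, abs_tol : float
        Adaptive-step tolerances.  Defaults are tight because the
        downstream analyses (equilibrium cross-checks, landscape frames)
        assert agreement to 1e-6 or better.
    max_step : float, optional
        Upper bound on the internal step size.
    output_times : array-like, optional
        Sampling grid for the trajectory; default: 1501 uniform samples
        on [0, t_end].
    strategy_bounds : (float, float), optional
        Box constraints [u_min, u_max] on the strategy set U, enforced by
        projection.  Default: unbounded.
    extinction_threshold : float, optional
        Density floor; once a clone's density falls below it the clone is
        set to exactly 0 and frozen.  Default: none.
    """

    t_end: float
    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    max_step: Optional[float] = None
    output_times: Optional[Sequence[float]] = None
    strategy_bounds: Optional[tuple[float, float]] = None
    extinction_threshold: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.t_end > 0):
            raise StructuralError(f"t_end must be positive, got {self.t_end!r}")
        if not (self.rel_tol > 0 and self.abs_tol > 0):
            raise StructuralError("integration tolerances must be positive")
        if self.strategy_bounds is not None:
            lo, hi = self.strategy_bounds
            if not (lo < hi):
                raise StructuralError(f"strategy bounds must satisfy u_min < u_max, got {self.strategy_bounds!r}")

    def resolved_output_times(self, t0: float = 0.0) -> np.ndarray:
        if self.output_times is not None:
            times = np.asarray(self.output_times, dtype=float)
            if times.ndim != 1 or times.size < 1:
                raise StructuralError("output_times must be a non-empty 1-D sequence")
            return times
        return np.linspace(t0, self.t_end, 1501)


@dataclass
class Trajectory:
    """Sampled time series of a community: times (T,), u and x (T, n)."""

    times: np.ndarray
    u: np.ndarray
    x: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def n_clones(self) -> int:
        return self.u.shape[1]

    def community_at(self, t: float, k: Optional[Sequence[float]] = None) -> CommunityState:
        """Community linearly interpolated from the sampled series at time t."""
        if t < self.times[0] or t > self.times[-1]:
            raise ValueError(
                f"time {t} outside trajectory range [{self.times[0]}, {self.times[-1]}]"
            )
        if k is None:
            k = self.metadata.get("clone_k", [0.0] * self.n_clones)
        u = [float(np.interp(t, self.times, self.u[:, i])) for i in range(self.n_clones)]
        x = [float(np.interp(t, self.times, self.x[:, i])) for i in range(self.n_clones)]
        return CommunityState.from_arrays(u, x, k, t)

    def final_community(self) -> CommunityState:
        k = self.metadata.get("clone_k", [0.0] * self.n_clones)
        return CommunityState.from_arrays(self.u[-1], self.x[-1], k, float(self.times[-1]))

    # -- serialization ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per (time, clone)."""
        T, n = self.u.shape
        return pd.DataFrame(
            {
                "time": np.repeat(self.times, n),
                "clone_id": np.tile(np.arange(n), T),
                "u": self.u.ravel(),
                "x": self.x.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path=None):
        doc = {
            "times": self.times.tolist(),
            "u": self.u.tolist(),
            "x": self.x.tolist(),
            "metadata": self.metadata,
        }
        text = json.dumps(doc)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None

    @classmethod
    def from_json(cls, source) -> "Trajectory":
        if isinstance(source, (str, bytes)) and not str(source).lstrip().startswith("{"):
            with open(source) as fh:
                doc = json.load(fh)
        elif isinstance(source, (str, bytes)):
            doc = json.loads(source)
        else:
            doc = json.load(source)
        return cls(
            times=np.asarray(doc["times"], dtype=float),
            u=np.asarray(doc["u"], dtype=float),
            x=np.asarray(doc["x"], dtype=float),
            metadata=doc.get("metadata", {}),
        )


# ---------------------------------------------------------------------------
# Fitness gradient and right-hand side
# ---------------------------------------------------------------------------

def fitness_gradient(
    model: GFunctionModel,
    community: CommunityState,
    clone_index: int,
    t: Optional[float] = None,
    method: str = "analytic",
) -> float:
    """dG/dv at the focal clone's own strategy, community held fixed.

    ``method='analytic'`` uses the model's closed-form derivative;
    ``method='central_difference'`` uses a second-order central difference
    with step ``1e-6 * max(1, |v|)`` (also the independent cross-check of
    the analytic form in the test-suite).
    """
    if not (0 <= clone_index < community.n_clones):
        raise StructuralError(f"clone_index {clone_index} out of range")
    if t is None:
        t = community.t
    u, x = community.u, community.x
    v = float(u[clone_index])
    if method == "analytic":
        if not getattr(model, "has_analytic_gradient", False):
            raise CapabilityError(
                f"model {type(model).__name__} does not supply an analytic gradient; "
                "use method='central_difference'"
            )
        return float(model.dg_dv(v, u, x, t))
    if method == "central_difference":
        h = _FD_STEP * max(1.0, abs(v))
        return float((model.g(v + h, u, x, t) - model.g(v - h, u, x, t)) / (2.0 * h))
    raise ValueError(f"unknown gradient method {method!r}")


def eco_evo_rhs(
    model: GFunctionModel,
    community: CommunityState,
    t: Optional[float] = None,
    gradient_method: str = "analytic",
) -> tuple[np.ndarray, np.ndarray]:
    """Time derivatives (dx, du) of the community under the model.

    dx_i/dt = x_i G(u_i, u, x, t);  du_i/dt = k_i dG/dv|_{u_i}.  A clone
    with zero density has dx_i/dt = 0 exactly.
    """
    if t is None:
        t = community.t
    u, x, k = community.u, community.x, community.k
    dx = np.empty_like(x)
    du = np.empty_like(u)
    for i in range(community.n_clones):
        gi = float(model.g(float(u[i]), u, x, t))
        grad = fitness_gradient(model, community, i, t, method=gradient_method)
        if not (math.isfinite(gi) and math.isfinite(grad)):
            raise NumericalDomainError(
                f"non-finite fitness or gradient for clone {i} at t={t}: G={gi}, dG/dv={grad}"
            )
        dx[i] = x[i] * gi
        du[i] = k[i] * grad
    return dx, du


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _segment_bounds(model: GFunctionModel, t0: float, t_end: float) -> list[float]:
    bps = [b for b in model.time_breakpoints() if t0 < b < t_end and math.isfinite(b)]
    return [t0, *sorted(bps), t_end]


def simulate(
    model: GFunctionModel,
    initial: CommunityState,
    spec: SimulationSpec,
    gradient_method: str = "analytic",
) -> Trajectory:
    """Integrate the coupled dynamics and sample them on the output grid.

    Deterministic given (model, initial, spec).  Treatment-style forcing
    discontinuities are handled by splitting the integration at each
    breakpoint; within a segment that ends at a breakpoint b the model is
    evaluated at min(t, nextafter(b, -inf)) so the post-b forcing is never
    sampled early.
    """
    n = initial.n_clones
    k = initial.k
    t0 = float(initial.t)
    out_times = spec.resolved_output_times(t0)
    if out_times[0] < t0 - 1e-12 or out_times[-1] > spec.t_end + 1e-12:
        raise StructuralError("output_times must lie within [t0, t_end]")

    bounds = spec.strategy_bounds
    thr = spec.extinction_threshold
    alive = np.ones(n, dtype=bool)
    if thr is not None:
        alive = initial.x >= thr

    def make_rhs(t_cap: float) -> Callable:
        def rhs(t: float, y: np.ndarray) -> np.ndarray:
            tt = min(t, t_cap)
            x = np.where(y[:n] > 0, y[:n], 0.0)
            u = y[n:]
            if bounds is not None:
                u = np.clip(u, bounds[0], bounds[1])
            x_eff = np.where(alive, x, 0.0)
            dx = np.empty(n)
            du = np.empty(n)
            for i in range(n):
                if not alive[i]:
                    dx[i] = 0.0
                    du[i] = 0.0
                    continue
                gi = model.g(float(u[i]), u, x_eff, tt)
                if gradient_method == "analytic" and getattr(model, "has_analytic_gradient", False):
                    grad = model.dg_dv(float(u[i]), u, x_eff, tt)
                else:
                    h = _FD_STEP * max(1.0, abs(float(u[i])))
                    grad = (model.g(float(u[i]) + h, u, x_eff, tt)
                            - model.g(float(u[i]) - h, u, x_eff, tt)) / (2.0 * h)
                dx[i] = x_eff[i] * float(gi)
                du[i] = k[i] * float(grad)
                if bounds is not None:
                    if (u[i] >= bounds[1] and du[i] > 0) or (u[i] <= bounds[0] and du[i] < 0):
                        du[i] = 0.0
            if not (np.all(np.isfinite(dx)) and np.all(np.isfinite(du))):
                bad = int(np.argmax(~(np.isfinite(dx) & np.isfinite(du))))
                raise NumericalDomainError(f"non-finite derivative for clone {bad} at t={t}")
            return np.concatenate([dx, du])

        return rhs

    y = np.concatenate([initial.x, initial.u])
    rec_t: list[float] = []
    rec_y: list[np.ndarray] = []
    if out_times[0] <= t0 + 1e-12:
        rec_t.append(t0)
        rec_y.append(y.copy())
        first_needed = 1
    else:
        first_needed = 0

    segs = _segment_bounds(model, t0, float(spec.t_end))
    breakset = set(segs[1:-1])
    seg_stats = []
    idx = first_needed
    for lo, hi in zip(segs[:-1], segs[1:]):
        t_cap = np.nextafter(hi, lo) if hi in breakset else math.inf
        rhs = make_rhs(t_cap)
        want = []
        while idx < len(out_times) and out_times[idx] <= hi + 1e-12:
            want.append(min(float(out_times[idx]), hi))
            idx += 1
        t_eval = sorted(set(want) | {hi})
        kwargs = {}
        if spec.max_step is not None:
            kwargs["max_step"] = spec.max_step
        while True:
            sol = solve_ivp(
                rhs,
                (lo, hi),
                y,
                method="DOP853",
                t_eval=t_eval,
                rtol=spec.rel_tol,
                atol=spec.abs_tol,
                dense_output=thr is not None,
                events=(_extinction_event(n, thr, alive) if thr is not None else None),
                **kwargs,
            )
            if not sol.success:
                raise NumericalDomainError(
                    f"integrator failed on [{lo}, {hi}]: {sol.message}; "
                    f"last good state t={sol.t[-1] if sol.t.size else lo}"
                )
            if thr is not None and sol.status == 1:  # extinction event fired
                t_ev = float(sol.t_events[0][0])
                y_ev = sol.sol(t_ev)
                xs = y_ev[:n]
                dying = alive & (xs <= thr * (1 + 1e-9))
                xs = np.where(dying, 0.0, xs)
                alive = alive & ~dying
                for tt, yy in zip(sol.t, sol.y.T):
                    if tt < t_ev and tt in want:
                        rec_t.append(tt)
                        rec_y.append(yy.copy())
                want = [w for w in want if w >= t_ev]
                t_eval = sorted(set(want) | {hi})
                y = np.concatenate([xs, y_ev[n:]])
                lo = t_ev
                continue
            break
        for tt, yy in zip(sol.t, sol.y.T):
            if tt in want:
                rec_t.append(tt)
                rec_y.append(yy.copy())
        y = sol.y[:, -1].copy()
        seg_stats.append({"span": [lo, hi], "nfev": int(sol.nfev), "status": int(sol.status)})
        logger.info(
            "segment [%g, %g]: %d rhs evaluations, status %d", lo, hi, sol.nfev, sol.status
        )

    times = np.asarray(rec_t)
    Y = np.vstack(rec_y)
    x_series = Y[:, :n]
    u_series = Y[:, n:]
    clipped = int(np.sum(x_series < 0))
    worst_neg = float(x_series.min()) if clipped else 0.0
    x_series = np.clip(x_series, 0.0, None)
    if bounds is not None:
        u_series = np.clip(u_series, bounds[0], bounds[1])

    final = CommunityState.from_arrays(u_series[-1], x_series[-1], k, float(times[-1]))
    dxf, duf = eco_evo_rhs(model, final, gradient_method=gradient_method)
    residual = float(max(np.max(np.abs(dxf)), np.max(np.abs(duf))))

    meta = {
        "model_family": model.family,
        "params": model.params_dict(),
        "clone_k": k.tolist(),
        "spec": {
            "t_end": spec.t_end,
            "rel_tol": spec.rel_tol,
            "abs_tol": spec.abs_tol,
            "max_step": spec.max_step,
            "strategy_bounds": list(bounds) if bounds is not None else None,
            "extinction_threshold": thr,
        },
        "segments": seg_stats,
        "negative_density_samples_clipped": clipped,
        "worst_negative_density": worst_neg,
        "final_rhs_norm": residual,
        "gradient_method": gradient_method,
    }
    return Trajectory(times=times, u=u_series, x=x_series, metadata=meta)


def _extinction_event(n: int, thr: float, alive: np.ndarray):
    def event(t, y):
        xs = y[:n]
        live = xs[alive] if alive.any() else np.array([1.0])
        return float(np.min(live) - thr)

    event.terminal = True
    event.direction = -1.0
    return [event]


def run_to_stationarity(
    model: GFunctionModel,
    initial: CommunityState,
    residual_tol: float = 1e-8,
    chunk: float = 2000.0,
    max_time: float = 1e5,
    rel_tol: float = 1e-10,
    abs_tol: float = 1e-12,
) -> tuple[CommunityState, float, float]:
    """Integrate in chunks until the RHS max-norm drops below residual_tol.

    Returns (final community, residual, total time integrated).  Raises
    if the residual has not converged by ``max_time``.
    """
    state = initial
    elapsed = 0.0
    while elapsed < max_time:
        spec = SimulationSpec(
            t_end=state.t + chunk,
            rel_tol=rel_tol,
            abs_tol=abs_tol,
            output_times=[state.t, state.t + chunk],
        )
        traj = simulate(model, state, spec)
        state = traj.final_community()
        elapsed += chunk
        dx, du = eco_evo_rhs(model, state)
        residual = float(max(np.max(np.abs(dx)), np.max(np.abs(du))))
        if residual < residual_tol:
            return state, residual, elapsed
    raise NumericalDomainError(
        f"no stationary state within t={max_time} (residual {residual:.3e} > {residual_tol:.1e})"
    )
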