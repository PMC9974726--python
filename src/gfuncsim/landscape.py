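"""Adaptive-landscape computation: G(v) over a strategy grid.

An adaptive landscape is the fitness G of a (rare) focal cell as a
function of its strategy v, with the resident community (u, x) held
fixed.  As the community evolves the landscape deforms; stacking frames
over time yields the familiar 3-D landscape surface.  Peaks are the
strategies selection climbs towards; a valley appearing at the resident
strategy (e.g. at treatment onset) signals disruptive selection and the
potential for diversification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import CommunityState, Trajectory
from .exceptions import NumericalDomainError, StructuralError
from .models import GFunctionModel

__all__ = ["Extremum", "LandscapeFrame", "default_grid", "landscape_frame", "landscape_over_time"]

#: local maxima within this absolute fitness of the global grid maximum are
#: flagged as co-peaks (equal-fitness peaks, the diversification signature)
CO_PEAK_ATOL = 1e-9


def default_grid(v_min: float = -10.0, v_max: float = 10.0, n: int = 401) -> np.ndarray:
    """Default strategy grid covering all bundled scenarios with margin."""
    return np.linspace(v_min, v_max, n)


@dataclass(frozen=True)
class Extremum:
    v: float
    G: float
    kind: str  # "max" | "min"
    co_peak: bool = False


@dataclass
class LandscapeFrame:
    """Fitness over a strategy grid at one instant, with located extrema.

    Extrema are detected from sign changes of the discrete slope and
    refined by a local quadratic fit; grid boundary points are never
    reported (a boundary extremum cannot be distinguished from grid
    truncation).
    """

    t: float
    v_grid: np.ndarray
    g_values: np.ndarray
    extrema: list[Extremum] = field(default_factory=list)

    @property
    def maxima(self) -> list[Extremum]:
        return [e for e in self.extrema if e.kind == "max"]

    @property
    def minima(self) -> list[Extremum]:
        return [e for e in self.extrema if e.kind == "min"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "v": self.v_grid, "G": self.g_values})

    def to_json(self) -> str:
        return json.dumps(
            {
                "t": self.t,
                "v_grid": self.v_grid.tolist(),
                "g_values": self.g_values.tolist(),
                "extrema": [
                    {"v": e.v, "G": e.G, "kind": e.kind, "co_peak": e.co_peak}
                    for e in self.extrema
                ],
            }
        )


def _refine(v: np.ndarray, g: np.ndarray, j: int) -> tuple[float, float]:
    """Vertex of the parabola through the three grid points around j."""
    vs, gs = v[j - 1 : j + 2], g[j - 1 : j + 2]
    a, b, c = np.polyfit(vs, gs, 2)
    if a == 0:
        return float(v[j]), float(g[j])
    v_star = -b / (2.0 * a)
    if not (vs[0] <= v_star <= vs[2]):
        return float(v[j]), float(g[j])
    return float(v_star), float(a * v_star ** 2 + b * v_star + c)


def _locate_extrema(v: np.ndarray, g: np.ndarray) -> list[Extremum]:
    slopes = np.diff(g)
    signs = np.sign(slopes)
    # carry the previous sign through flat stretches so plateaus do not
    # generate spurious extrema
    for i in range(1, signs.size):
        if signs[i] == 0:
            signs[i] = signs[i - 1]
    extrema: list[Extremum] = []
    for j in range(1, v.size - 1):
        s_prev, s_next = signs[j - 1], signs[j]
        if s_prev > 0 and s_next < 0:
            vv, gg = _refine(v, g, j)
            extrema.append(Extremum(vv, gg, "max"))
        elif s_prev < 0 and s_next > 0:
            vv, gg = _refine(v, g, j)
            extrema.append(Extremum(vv, gg, "min"))
    maxima = [e for e in extrema if e.kind == "max"]
    if maxima:
        g_top = max(e.G for e in maxima)
        n_top = sum(1 for e in maxima if abs(e.G - g_top) <= CO_PEAK_ATOL)
        if n_top > 1:
            extrema = [
                Extremum(e.v, e.G, e.kind, co_peak=(e.kind == "max" and abs(e.G - g_top) <= CO_PEAK_ATOL))
                for e in extrema
            ]
    return extrema


def landscape_frame(
    model: GFunctionModel,
    community: CommunityState,
    t: Optional[float] = None,
    v_grid: Optional[np.ndarray] = None,
) -> LandscapeFrame:
    """Evaluate G(v) on the grid with the community held fixed at time t."""
    if t is None:
        t = community.t
    if v_grid is None:
        v_grid = default_grid()
    v_grid = np.asarray(v_grid, dtype=float)
    if v_grid.ndim != 1 or v_grid.size < 3:
        raise StructuralError("v_grid must be a 1-D grid with at least 3 points")
    if np.any(np.diff(v_grid) <= 0):
        raise StructuralError("v_grid must be strictly increasing")
    g = np.asarray(model.g(v_grid, community.u, community.x, t), dtype=float)
    if not np.all(np.isfinite(g)):
        bad = int(np.argmax(~np.isfinite(g)))
        raise NumericalDomainError(f"non-finite fitness at grid point v={v_grid[bad]}")
    return LandscapeFrame(t=float(t), v_grid=v_grid, g_values=g, extrema=_locate_extrema(v_grid, g))


def landscape_over_time(
    model: GFunctionModel,
    trajectory: Trajectory,
    v_grid: Optional[np.ndarray] = None,
    times: Optional[Sequence[float]] = None,
) -> list[LandscapeFrame]:
    """One landscape frame per requested time, community interpolated
    linearly from the trajectory.  Times must lie within the trajectory's
    sampled range."""
    if times is None:
        times = trajectory.times
    frames = []
    for t in sorted(float(t) for t in times):
        community = trajectory.community_at(t)  # raises on out-of-range
        frames.append(landscape_frame(model, community, t, v_grid))
    return frames


def frames_to_frame(frames: Sequence[LandscapeFrame]) -> pd.DataFrame:
    """Concatenate frames into one long table (t, v, G): the 3-D surface."""
    return pd.concat([f.to_frame() for f in frames], ignore_index=True)
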