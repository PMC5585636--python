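"""Kinetic model of de novo fat production and desaturation.

De novo fat is produced at a constant rate and starts saturated; the
desaturase enzyme pool (SCD) is induced by saturated fat and decays, and
unsaturated fat accumulates in proportion to the enzyme:

    dF/dt = a            total fat (linear production)
    dU/dt = E            unsaturated fat
    dE/dt = b*S - c*E    enzyme, with S = F - U the saturated pool

Melting temperature falls linearly with the unsaturated proportion:
``Tm = T_delta * (S / F) + T_U``, so Tm spans ``[T_U, T_U + T_delta]``.
The (S, E) subsystem is affine linear with steady state ``S* = a*c/b``,
``E* = a``; both printed parameter presets share ``S* = 100``, the model
counterpart of the common long-feed Tm floor.  Time is measured in days
(days on feed).

Defaults ``a = 1`` (fixes the mass unit), ``F(0) = 1``, ``U(0) = E(0) = 0``,
``T_delta = 14`` °C and ``T_U = 30`` °C make the default curve span roughly
44 to 30 °C, consistent with observed subcutaneous/intramuscular Tm ranges;
all are configurable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .assoc import TmRecord, fisher_exact_2x2

__all__ = [
    "DesatParams",
    "DesatState",
    "FitResult",
    "GroupCount",
    "Trajectory",
    "FAST",
    "SLOW",
    "PRESETS",
    "count_above_threshold",
    "fit_desat_params",
    "interpolate_params",
    "simulate_desaturation",
    "smooth_tm_dof",
    "steady_state",
    "tm_from_state",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DesatParams:
    """Model parameters.

    a: de novo fat production rate (fat mass / day); b: enzyme induction
    coefficient (enzyme units per fat mass per day); c: enzyme decay rate
    (/day); T_delta: melting-range width (°C); T_U: fully-unsaturated
    asymptote temperature (°C).
    """

    a: float = 1.0
    b: float = 1e-3
    c: float = 1e-1
    T_delta: float = 14.0
    T_U: float = 30.0

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError(f"a must be >= 0, got {self.a}")
        if self.b <= 0 or self.c <= 0:
            raise ValueError(f"b and c must be > 0, got b={self.b}, c={self.c}")
        if self.T_delta <= 0:
            raise ValueError(f"T_delta must be > 0, got {self.T_delta}")


#: Fast enzyme response (resembles TCAP 20 homozygotes).
FAST = DesatParams(b=1e-3, c=1e-1)
#: Slow enzyme response (resembles TCAP 10 homozygotes).
SLOW = DesatParams(b=1e-4, c=1e-2)
PRESETS: dict[str, DesatParams] = {"fast": FAST, "slow": SLOW}


def interpolate_params(p: DesatParams, q: DesatParams) -> DesatParams:
    """Geometric-mean interpolation of the rate constants b and c.

    Used as the default heterozygote kinetics between two homozygote
    presets; purely a modelling convention.
    """
    return replace(p, b=math.sqrt(p.b * q.b), c=math.sqrt(p.c * q.c))


@dataclass(frozen=True)
class DesatState:
    """State at one time point; the saturated pool S = F - U is derived."""

    t: float
    F: float
    U: float
    E: float

    def __post_init__(self) -> None:
        if self.U < 0 or self.U > self.F * (1 + 1e-12):
            raise ValueError(f"need 0 <= U <= F, got U={self.U}, F={self.F}")
        if self.E < 0:
            raise ValueError(f"need E >= 0, got {self.E}")

    @property
    def S(self) -> float:
        return self.F - self.U


DEFAULT_INIT = DesatState(t=0.0, F=1.0, U=0.0, E=0.0)


@dataclass
class Trajectory:
    """Simulated states on a strictly increasing time grid, plus Tm."""

    t: np.ndarray
    F: np.ndarray
    U: np.ndarray
    E: np.ndarray
    params: DesatParams

    @property
    def S(self) -> np.ndarray:
        return self.F - self.U

    @property
    def tm(self) -> np.ndarray:
        return self.params.T_delta * (self.S / self.F) + self.params.T_U

    def state(self, i: int) -> DesatState:
        return DesatState(
            t=float(self.t[i]), F=float(self.F[i]), U=float(self.U[i]), E=float(self.E[i])
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"t": self.t, "F": self.F, "U": self.U, "S": self.S, "E": self.E, "Tm": self.tm}
        )


def _rk4_step(y: np.ndarray, dt: float, params: DesatParams) -> np.ndarray:
    a, b, c = params.a, params.b, params.c

    def deriv(state: np.ndarray) -> np.ndarray:
        F, U, E = state
        return np.array([a, E, b * (F - U) - c * E])

    k1 = deriv(y)
    k2 = deriv(y + 0.5 * dt * k1)
    k3 = deriv(y + 0.5 * dt * k2)
    k4 = deriv(y + dt * k3)
    return y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)


def simulate_desaturation(
    params: DesatParams,
    init: DesatState = DEFAULT_INIT,
    t_grid: Optional[Sequence[float]] = None,
    t_max: float = 300.0,
    dt: float = 0.25,
) -> Trajectory:
    """Integrate the model with a fixed-step 4th-order Runge-Kutta scheme.

    ``t_grid`` (strictly increasing, starting at ``init.t``) selects the
    output points; each interval is sub-stepped so no step exceeds ``dt``.
    The model is non-stiff at the printed parameter scales, so the fixed
    step is both accurate and deterministic.  Should roundoff drive U above
    F it is clamped (and the clamp logged); conservation S + U = F then
    holds exactly at every grid point.
    """
    if t_grid is None:
        n = int(round((t_max - init.t) / dt))
        t_grid = init.t + dt * np.arange(n + 1)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    if not math.isclose(t_grid[0], init.t, abs_tol=1e-12):
        raise ValueError(f"t_grid must start at init.t = {init.t}")
    out = np.empty((len(t_grid), 3))
    y = np.array([init.F, init.U, init.E], dtype=float)
    out[0] = y
    clamped = False
    for i in range(1, len(t_grid)):
        span = t_grid[i] - t_grid[i - 1]
        n_sub = max(1, int(math.ceil(span / dt - 1e-12)))
        h = span / n_sub
        for _ in range(n_sub):
            y = _rk4_step(y, h, params)
            if y[1] > y[0]:
                clamped = True
                y[1] = y[0]
            if y[1] < 0:
                y[1] = 0.0
            if y[2] < 0:
                y[2] = 0.0
        out[i] = y
    if clamped:
        logger.warning("simulate_desaturation: U clamped to F during integration")
    return Trajectory(
        t=t_grid, F=out[:, 0], U=out[:, 1], E=out[:, 2], params=params
    )


def steady_state(params: DesatParams) -> tuple[float, float]:
    """Fixed point of the (S, E) subsystem: ``S* = a*c/b``, ``E* = a``.

    Setting dS/dt = a - E = 0 gives E* = a, and dE/dt = 0 then gives
    S* = c E* / b.  Requires b > 0 (no finite steady state otherwise).
    """
    if params.b <= 0:
        raise ValueError("no finite steady state for b <= 0")
    return (params.a * params.c / params.b, params.a)


def tm_from_state(state: DesatState, T_delta: float = 14.0, T_U: float = 30.0) -> float:
    """Melting temperature of the current fat pool: ``T_delta*(S/F) + T_U``."""
    if state.F <= 0:
        raise ValueError("Tm undefined for F <= 0 (no fat present)")
    return T_delta * (state.S / state.F) + T_U


@dataclass(frozen=True)
class FitResult:
    params: DesatParams
    rss: float
    success: bool
    message: str
    free: tuple[str, ...]


def fit_desat_params(
    observations: Sequence[tuple[float, float]],
    free: Sequence[str] = ("b", "c"),
    fixed: Optional[DesatParams] = None,
    init: Optional[dict[str, float]] = None,
    seed: Optional[int] = None,
    init_state: DesatState = DEFAULT_INIT,
    dt: float = 0.25,
) -> FitResult:
    """Least-squares fit of the Tm(DOF) curve to (DOF, Tm) observations.

    ``free`` selects the parameters to estimate among b, c, T_delta, T_U
    (a and the initial state stay fixed; a only sets the mass unit).  Rate
    constants are optimised on a log10 scale to keep them positive.  The
    fit minimises the residual sum of squares of model Tm evaluated at the
    observed DOF (one simulation per objective evaluation, linear
    interpolation on a fixed grid).  Deterministic given the initial guess;
    ``seed`` is accepted for interface uniformity and reserved for
    multi-start extensions.
    """
    del seed  # single-start deterministic optimisation
    allowed = {"b", "c", "T_delta", "T_U"}
    free = tuple(free)
    if not free or any(f not in allowed for f in free):
        raise ValueError(f"free parameters must be a non-empty subset of {allowed}")
    obs = np.asarray(observations, dtype=float)
    if obs.ndim != 2 or obs.shape[1] != 2:
        raise ValueError("observations must be (DOF, Tm) pairs")
    if obs.shape[0] < len(free) + 1:
        raise ValueError(
            f"under-determined: {obs.shape[0]} observations for {len(free)} "
            f"free parameters"
        )
    dof, tm_obs = obs[:, 0], obs[:, 1]
    if np.unique(dof).size < 2:
        raise ValueError("observations must span at least 2 distinct DOF values")
    base = fixed if fixed is not None else DesatParams()
    guess = dict(init or {})
    defaults = {"b": base.b, "c": base.c, "T_delta": base.T_delta, "T_U": base.T_U}
    x0 = []
    for name in free:
        value = guess.get(name, defaults[name])
        x0.append(math.log10(value) if name in ("b", "c") else value)

    t_hi = float(dof.max())

    def params_from(x: np.ndarray) -> DesatParams:
        kv = dict(defaults)
        for name, value in zip(free, x):
            kv[name] = 10.0 ** value if name in ("b", "c") else value
        return DesatParams(a=base.a, **kv)

    def residuals(x: np.ndarray) -> np.ndarray:
        p = params_from(x)
        traj = simulate_desaturation(p, init=init_state, t_max=t_hi, dt=dt)
        model_tm = np.interp(dof, traj.t, traj.tm)
        return model_tm - tm_obs

    result = least_squares(residuals, np.asarray(x0, dtype=float), method="lm")
    fitted = params_from(result.x)
    return FitResult(
        params=fitted,
        rss=float(np.sum(result.fun**2)),
        success=bool(result.success),
        message=str(result.message),
        free=free,
    )


def smooth_tm_dof(
    points: Sequence[tuple[float, float]],
    span: float = 100.0,
    mode: str = "bandwidth",
    grid: Optional[Sequence[float]] = None,
    n_grid: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Locally weighted linear regression of Tm on DOF (tricube weights).

    ``span`` is a bandwidth in DOF days by default (``mode="bandwidth"``);
    with ``mode="fraction"`` it is the fraction of points in each local
    window, as in classical lowess.  Returns ``(grid, smoothed)`` on an
    even DOF grid.  A local linear smoother reproduces straight-line data
    exactly for any span, and interpolates the data in the small-span limit
    on distinct abscissae.
    """
    if span <= 0:
        raise ValueError(f"span must be positive, got {span}")
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 5:
        raise ValueError("need at least 5 (DOF, Tm) points")
    x, y = pts[:, 0], pts[:, 1]
    if grid is None:
        grid = np.linspace(x.min(), x.max(), n_grid)
    grid = np.asarray(grid, dtype=float)
    if mode == "fraction":
        if not 0 < span <= 1:
            raise ValueError("fractional span must lie in (0, 1]")
        k = max(2, int(math.ceil(span * len(x))))
    elif mode != "bandwidth":
        raise ValueError(f"unknown mode {mode!r}")
    smoothed = np.empty_like(grid)
    for i, x0 in enumerate(grid):
        d = np.abs(x - x0)
        if mode == "fraction":
            h = np.partition(d, k - 1)[k - 1]
        else:
            h = span
        # Widen degenerate windows until they hold two distinct points.
        h = max(h, 1e-12)
        while np.count_nonzero(d < h) < 2:
            h *= 2.0
        w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
        inside = w > 0
        if np.count_nonzero(inside) < 2:
            w = np.where(d <= d.min(), 1.0, 0.0)
            inside = w > 0
        sw = w.sum()
        xm = (w * x).sum() / sw
        ym = (w * y).sum() / sw
        sxx = (w * (x - xm) ** 2).sum()
        if sxx <= 0:
            smoothed[i] = ym
        else:
            beta = (w * (x - xm) * (y - ym)).sum() / sxx
            smoothed[i] = ym + beta * (x0 - xm)
    return grid, smoothed


@dataclass(frozen=True)
class GroupCount:
    group: str
    k_above: int
    n_total: int
    empty: bool = False


def count_above_threshold(
    records_by_group: dict[str, Iterable[TmRecord]],
    dof_min: float = 100.0,
    tm_threshold: float = 39.0,
) -> tuple[dict[str, GroupCount], Optional[float]]:
    """Per-group counts of animals remaining above a Tm threshold late in feeding.

    Counts records with DOF > ``dof_min``; ``k_above`` of those with
    Tm > ``tm_threshold``.  For exactly two groups a Fisher exact p-value
    on the resulting 2x2 (above/not-above by group) is returned as well.
    """
    counts: dict[str, GroupCount] = {}
    for group, records in records_by_group.items():
        late = [r for r in records if r.dof > dof_min and r.tm is not None]
        k = sum(1 for r in late if r.tm > tm_threshold)
        counts[group] = GroupCount(group, k, len(late), empty=not late)
    p: Optional[float] = None
    groups = sorted(counts)
    if len(groups) == 2 and all(not counts[g].empty for g in groups):
        g1, g2 = (counts[g] for g in groups)
        p = fisher_exact_2x2(
            [[g1.k_above, g1.n_total - g1.k_above], [g2.k_above, g2.n_total - g2.k_above]]
        )
    return counts, p
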