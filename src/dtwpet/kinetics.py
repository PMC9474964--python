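"""Irreversible two-tissue compartment (2T3k) kinetics for dynamic FDG PET.

The model describes tracer exchange between plasma and two tissue
compartments (free and phosphorylated FDG)::

    dC1/dt = K1*Cp(t) - (k2 + k3)*C1(t)
    dC2/dt = k3*C1(t)                       (k4 = 0, irreversible)

and the measured voxel/ROI signal::

    C_PET(t) = Vb*Cp(t) + (1 - Vb)*(C1(t) + C2(t))

With theta = k2 + k3 the solution has the closed form

    C1 + C2 = Ki * int_0^t Cp + (K1*k2/theta) * (exp(-theta t) (*) Cp)(t)

where ``(*)`` is causal convolution and Ki = K1*k3/(k2+k3) is the net
influx rate.  Input functions are represented as piecewise-linear curves,
so the convolution is evaluated analytically per segment rather than on a
discretised grid; the forward model is therefore exact for a given
piecewise-linear Cp.

All times are minutes internally; rates are 1/min, K1 and Ki are
mL/g/min, activity concentrations kBq/mL.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "FrameSchedule",
    "TimeActivityCurve",
    "InputFunction",
    "KineticParams",
    "FitResult",
    "build_frame_schedule",
    "solve_2t3k",
    "frame_average",
    "model_tac",
    "fit_2t3k",
    "net_influx_rate",
    "DEFAULT_FRAME_BLOCKS",
    "DEFAULT_BOUNDS",
]

#: Standard 66-frame dynamic acquisition: 24x5s, 6x10s, 6x30s, 6x60s, 24x120s.
DEFAULT_FRAME_BLOCKS: tuple[tuple[int, int], ...] = (
    (24, 5),
    (6, 10),
    (6, 30),
    (6, 60),
    (24, 120),
)

#: Physiologic optimizer box: K1, k2, k3 in [0, 5], Vb in [0, 1].
DEFAULT_BOUNDS: tuple[tuple[float, float], ...] = (
    (0.0, 5.0),
    (0.0, 5.0),
    (0.0, 5.0),
    (0.0, 1.0),
)

_MULTISTART_INITS: tuple[tuple[float, float, float, float], ...] = (
    (0.1, 0.1, 0.05, 0.05),
    (0.5, 0.5, 0.1, 0.05),
    (0.02, 0.2, 0.01, 0.1),
    (0.3, 0.05, 0.002, 0.02),
)


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered, non-overlapping acquisition frames, times in minutes."""

    start: np.ndarray
    end: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.start, dtype=float)
        end = np.asarray(self.end, dtype=float)
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "end", end)
        if start.ndim != 1 or start.shape != end.shape or start.size == 0:
            raise ValueError("schedule needs matching, nonempty start/end arrays")
        if np.any(start < 0):
            raise ValueError("frame times must be >= 0")
        if np.any(end <= start):
            raise ValueError("each frame must satisfy t_start < t_end")
        if np.any(np.diff(start) <= 0) or np.any(start[1:] < end[:-1] - 1e-12):
            raise ValueError("frames must be sorted and non-overlapping")

    def __len__(self) -> int:
        return self.start.size

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.start + self.end)

    @property
    def durations(self) -> np.ndarray:
        return self.end - self.start

    @property
    def span(self) -> tuple[float, float]:
        return float(self.start[0]), float(self.end[-1])

    def subset(self, keep: np.ndarray) -> "FrameSchedule":
        keep = np.asarray(keep)
        return FrameSchedule(self.start[keep], self.end[keep])


def build_frame_schedule(
    blocks: Sequence[tuple[int, float]] = DEFAULT_FRAME_BLOCKS,
) -> FrameSchedule:
    """Build a contiguous schedule from ``(count, duration_seconds)`` blocks.

    Frames start at t=0 and are returned in minutes.
    """
    if not blocks:
        raise ValueError("empty framing specification")
    durations_s: list[float] = []
    for count, dur in blocks:
        if count < 1:
            raise ValueError(f"block count must be >= 1, got {count}")
        if dur <= 0:
            raise ValueError(f"frame duration must be > 0, got {dur}")
        durations_s.extend([float(dur)] * int(count))
    edges_min = np.concatenate([[0.0], np.cumsum(durations_s)]) / 60.0
    return FrameSchedule(edges_min[:-1], edges_min[1:])


@dataclass(frozen=True)
class TimeActivityCurve:
    """Per-frame mean activity concentration (kBq/mL) for a region or voxel."""

    schedule: FrameSchedule
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (len(self.schedule),):
            raise ValueError("one value per frame required")
        if not np.all(np.isfinite(values)):
            raise ValueError("TAC values must be finite")

    @property
    def midpoints(self) -> np.ndarray:
        return self.schedule.midpoints

    @property
    def has_negative(self) -> bool:
        """Measured data may carry small negatives; preserved but flagged."""
        return bool(np.any(self.values < 0))

    def subset(self, keep: np.ndarray) -> "TimeActivityCurve":
        keep = np.asarray(keep)
        return TimeActivityCurve(self.schedule.subset(keep), self.values[keep])


class InputFunction:
    """Piecewise-linear blood activity curve Cp(t), kBq/mL vs minutes.

    The curve is anchored at (0, 0) when the first knot is after t=0
    (no activity before injection), interpolated linearly between knots,
    held constant beyond the last knot, and zero for t < 0.  Integrals
    are exact for the piecewise-linear representation.
    """

    def __init__(self, times: np.ndarray, values: np.ndarray):
        times = np.asarray(times, dtype=float)
        values = np.asarray(values, dtype=float)
        if times.ndim != 1 or times.shape != values.shape or times.size < 2:
            raise ValueError("need matching 1-D times/values with >= 2 samples")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if times[0] < 0:
            raise ValueError("input function support starts at t >= 0")
        if np.any(values < -1e-9):
            raise ValueError("input function values must be nonnegative")
        values = np.clip(values, 0.0, None)
        if times[0] > 0:
            times = np.concatenate([[0.0], times])
            values = np.concatenate([[0.0], values])
        self.times = times
        self.values = values
        # cumulative exact integral at the knots
        self._cum = np.concatenate(
            [[0.0], np.cumsum(0.5 * (values[1:] + values[:-1]) * np.diff(times))]
        )

    def __call__(self, t: np.ndarray | float) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.interp(t, self.times, self.values)
        return np.where(t < 0, 0.0, out)

    def integral(self, t: np.ndarray | float) -> np.ndarray:
        """Exact integral of Cp from 0 to t (kBq*min/mL)."""
        t = np.asarray(t, dtype=float)
        tc = np.clip(t, 0.0, None)
        idx = np.clip(np.searchsorted(self.times, tc, side="right") - 1, 0, None)
        t0 = self.times[idx]
        base = self._cum[idx]
        partial = 0.5 * (self(tc) + self.values[idx]) * (tc - t0)
        # beyond the last knot the curve is held constant
        over = tc > self.times[-1]
        if np.any(over):
            partial = np.where(
                over, self.values[-1] * (tc - self.times[-1]), partial
            )
        return base + partial

    def auc(self, a: float, b: float) -> float:
        """Area under the curve on [a, b] minutes."""
        return float(self.integral(b) - self.integral(a))

    def exp_conv(self, theta: float, t: np.ndarray) -> np.ndarray:
        """Analytic causal convolution g(t) = int_0^t exp(-theta (t-s)) Cp(s) ds.

        Exact per piecewise-linear segment; evaluated stably for large
        theta*t by block-wise rescaling of the cumulative recurrence.
        """
        t = np.asarray(t, dtype=float)
        if theta < 0:
            raise ValueError("theta must be >= 0")
        if theta < 1e-12:
            return self.integral(t)
        tq = np.atleast_1d(t)
        tmax = float(tq.max(initial=0.0))
        knots = self.times[self.times <= tmax]
        grid = np.union1d(np.concatenate([knots, [0.0]]), np.clip(tq, 0.0, None))
        f = self(grid)
        dt = np.diff(grid)
        x = theta * dt
        f0 = f[:-1]
        slope = np.where(dt > 0, np.diff(f) / np.where(dt > 0, dt, 1.0), 0.0)
        em1 = np.expm1(-x)  # e^{-x} - 1
        e1 = -em1 / theta  # int_0^dt e^{-theta(dt-u)} du
        small = x < 1e-4
        e2 = np.where(
            small,
            dt * dt * (0.5 - x / 6.0 + x * x / 24.0),
            (x + em1) / theta**2,
        )  # int_0^dt e^{-theta(dt-u)} u du
        seg = f0 * e1 + slope * e2

        g = np.zeros_like(grid)
        n = grid.size
        start = 0
        max_span = 30.0 / theta  # keep exp factors within ~e^{30}
        while start < n - 1:
            stop = int(np.searchsorted(grid, grid[start] + max_span, side="right"))
            stop = min(max(stop, start + 2), n)
            tt = grid[start:stop]
            # g(t_j) = e^{-theta (t_j - t_0)} [ g(t_0) + sum_{i<j} seg_i e^{theta (t_{i+1} - t_0)} ]
            w = np.exp(theta * (tt[1:] - tt[0]))  # bounded by e^{30}
            csum = np.cumsum(seg[start : stop - 1] * w)
            g[start + 1 : stop] = (g[start] + csum) / w
            start = stop - 1

        out = np.interp(np.clip(tq, 0.0, None), grid, g)
        out = np.where(tq <= 0, 0.0, out)
        return out.reshape(t.shape) if t.ndim else out[0]

    def shifted(self, delay_min: float) -> "InputFunction":
        """Return the curve delayed by ``delay_min`` (Cp(t - delay)).

        Positive delay moves the curve later (zero-padded before t=0);
        negative delay moves it earlier, truncating what falls below 0.
        """
        new_t = self.times + delay_min
        if delay_min >= 0:
            return InputFunction(new_t, self.values.copy())
        keep = new_t > 0
        t0_val = float(np.interp(0.0, new_t, self.values))
        return InputFunction(
            np.concatenate([[0.0], new_t[keep]]),
            np.concatenate([[t0_val], self.values[keep]]),
        )


@dataclass(frozen=True)
class KineticParams:
    """2T3k micro-parameters; k4 fixed at 0 (irreversible trapping)."""

    K1: float  # mL/g/min
    k2: float  # 1/min
    k3: float  # 1/min
    Vb: float  # fraction
    k4: float = 0.0

    def __post_init__(self) -> None:
        if min(self.K1, self.k2, self.k3) < 0:
            raise ValueError("rate constants must be >= 0")
        if not 0.0 <= self.Vb <= 1.0:
            raise ValueError("Vb must lie in [0, 1]")
        if self.k4 != 0.0:
            raise ValueError("only the irreversible model (k4 = 0) is supported")

    @property
    def Ki(self) -> float:
        return net_influx_rate(self)

    def as_array(self) -> np.ndarray:
        return np.array([self.K1, self.k2, self.k3, self.Vb])


def net_influx_rate(params: "KineticParams | None" = None, K1: float = 0.0,
                    k2: float = 0.0, k3: float = 0.0) -> float:
    """Net FDG influx rate Ki = K1*k3/(k2 + k3), mL/g/min.

    Defined as 0 when k2 + k3 = 0 (no exchange beyond delivery).
    """
    if params is not None:
        K1, k2, k3 = params.K1, params.k2, params.k3
    if min(K1, k2, k3) < 0:
        raise ValueError("rates must be >= 0")
    theta = k2 + k3
    if theta == 0.0:
        return 0.0
    return K1 * k3 / theta


def solve_2t3k(
    input_fn: InputFunction,
    params: KineticParams,
    grid: np.ndarray,
) -> np.ndarray:
    """Evaluate the 2T3k forward model C_PET(t) on ``grid`` (minutes).

    Uses the analytic solution against the piecewise-linear input
    function, so there is no ODE discretisation error.
    """
    grid = np.asarray(grid, dtype=float)
    theta = params.k2 + params.k3
    cp = input_fn(grid)
    if theta < 1e-12:
        tissue = params.K1 * input_fn.integral(grid)
    else:
        ki = params.K1 * params.k3 / theta
        tissue = ki * input_fn.integral(grid) + (
            params.K1 * params.k2 / theta
        ) * input_fn.exp_conv(theta, grid)
    return params.Vb * cp + (1.0 - params.Vb) * tissue


def frame_average(
    curve: Callable[[np.ndarray], np.ndarray],
    schedule: FrameSchedule,
    n_sub: int = 32,
) -> TimeActivityCurve:
    """Average a continuous curve over each frame by sub-frame quadrature."""
    grid = _subframe_grid(schedule, n_sub)
    vals = np.asarray(curve(grid.ravel()), dtype=float).reshape(grid.shape)
    means = np.trapezoid(vals, grid, axis=1) / schedule.durations
    return TimeActivityCurve(schedule, means)


def _subframe_grid(schedule: FrameSchedule, n_sub: int) -> np.ndarray:
    frac = np.linspace(0.0, 1.0, n_sub + 1)
    return schedule.start[:, None] + schedule.durations[:, None] * frac[None, :]


def model_tac(
    input_fn: InputFunction,
    params: KineticParams,
    schedule: FrameSchedule,
    sampling: str = "average",
    n_sub: int = 8,
) -> TimeActivityCurve:
    """Forward-model frame values: frame averages (default) or midpoint samples."""
    if sampling == "midpoint":
        return TimeActivityCurve(
            schedule, solve_2t3k(input_fn, params, schedule.midpoints)
        )
    if sampling != "average":
        raise ValueError("sampling must be 'average' or 'midpoint'")
    grid = _subframe_grid(schedule, n_sub)
    flat = grid.ravel()
    order = np.argsort(flat, kind="stable")
    vals = np.empty_like(flat)
    vals[order] = solve_2t3k(input_fn, params, flat[order])
    vals = vals.reshape(grid.shape)
    means = np.trapezoid(vals, grid, axis=1) / schedule.durations
    return TimeActivityCurve(schedule, means)


def frame_weights(schedule: FrameSchedule, scheme: str = "duration") -> np.ndarray:
    """Objective weights per frame, normalised to sum to 1.

    ``duration`` weighting approximates count-variance weighting for
    decay-corrected data; ``uniform`` gives every frame equal say.
    """
    if scheme == "duration":
        w = schedule.durations.astype(float)
    elif scheme == "uniform":
        w = np.ones(len(schedule))
    else:
        raise ValueError(f"unknown weight scheme {scheme!r}")
    return w / w.sum()


@dataclass
class FitResult:
    """Outcome of a weighted 2T3k fit."""

    params: KineticParams
    weighted_rss: float
    weights: np.ndarray
    fitted: TimeActivityCurve
    converged: bool
    delay_min: float = 0.0
    n_starts: int = 1

    @property
    def Ki(self) -> float:
        return self.params.Ki


def fit_2t3k(
    tac: TimeActivityCurve,
    input_fn: InputFunction,
    weights: str | np.ndarray = "duration",
    inits: Sequence[Sequence[float]] | None = None,
    bounds: Sequence[tuple[float, float]] = DEFAULT_BOUNDS,
    sampling: str = "average",
    n_sub: int = 8,
) -> FitResult:
    """Fit (K1, k2, k3, Vb) by bounded weighted nonlinear least squares.

    Minimises chi^2 = sum_i w_i (C_PET(t_i) - C_t(t_i; p))^2 with a small
    multi-start grid; the best start by weighted RSS wins.  Degenerate
    inputs (all-zero TAC) return a zero-parameter result flagged as
    converged rather than raising, so callers can loop over regions.
    """
    if isinstance(weights, str):
        w = frame_weights(tac.schedule, weights)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != tac.values.shape or np.any(w <= 0):
            raise ValueError("weights must be positive, one per frame")
        w = w / w.sum()
    sqrt_w = np.sqrt(w)

    if np.allclose(tac.values, 0.0):
        zero = KineticParams(0.0, 0.0, 0.0, 0.0)
        fitted = TimeActivityCurve(tac.schedule, np.zeros_like(tac.values))
        return FitResult(zero, 0.0, w, fitted, converged=True)

    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    starts = _MULTISTART_INITS if inits is None else inits

    def residuals(x: np.ndarray) -> np.ndarray:
        p = KineticParams(*np.clip(x, lo, hi))
        model = model_tac(input_fn, p, tac.schedule, sampling=sampling, n_sub=n_sub)
        return sqrt_w * (tac.values - model.values)

    best = None
    any_converged = False
    for x0 in starts:
        x0 = np.clip(np.asarray(x0, dtype=float), lo, hi)
        try:
            sol = least_squares(
                residuals, x0, bounds=(lo, hi), method="trf",
                xtol=1e-10, ftol=1e-10, gtol=1e-10,
            )
        except Exception:  # pragma: no cover - optimizer pathologies
            continue
        rss = float(np.sum(sol.fun**2))
        any_converged = any_converged or bool(sol.success)
        if best is None or rss < best[0]:
            best = (rss, sol)
    if best is None:  # pragma: no cover
        zero = KineticParams(0.0, 0.0, 0.0, 0.0)
        fitted = TimeActivityCurve(tac.schedule, np.zeros_like(tac.values))
        return FitResult(zero, np.inf, w, fitted, converged=False)

    rss, sol = best
    params = KineticParams(*np.clip(sol.x, lo, hi))
    fitted = model_tac(input_fn, params, tac.schedule, sampling=sampling, n_sub=n_sub)
    return FitResult(
        params, rss, w, fitted,
        converged=any_converged, n_starts=len(list(starts)),
    )
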