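"""Simplified FDG quantification: SUV, FUR, and Patlak graphical analysis.

These are the single-scan (or linearised) surrogates of the net influx
rate Ki that the dual-time-window protocol is compared against:

* SUV  = C_PET(T) / (A/W) — uptake normalised by injected dose per body
  weight; needs no input function.
* FUR  = C_PET(T) / int_0^T Cp dt — uptake normalised by the plasma
  integral; a Ki surrogate that removes delivery variation.
* Patlak: for irreversible tracers, C_PET(T)/Cp(T) plotted against
  int_0^T Cp/Cp(T) becomes linear beyond the equilibrium time t*; the
  slope estimates Ki.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .kinetics import InputFunction, TimeActivityCurve

__all__ = ["StaticMeasure", "PatlakResult", "suv", "fur", "patlak"]

DEFAULT_WINDOW: tuple[float, float] = (50.0, 60.0)


@dataclass(frozen=True)
class StaticMeasure:
    """A single-scan uptake measure and the convention it was computed under."""

    kind: str  # "SUV" | "FUR"
    value: float
    window: tuple[float, float]  # minutes
    dose_bq: float | None = None
    weight_kg: float | None = None


@dataclass(frozen=True)
class PatlakResult:
    """Patlak regression outcome: Ki is the slope beyond t*."""

    Ki: float  # mL/g/min
    intercept: float
    t_star: float
    n_points: int
    r_squared: float


def _window_mean(tac: TimeActivityCurve, window: tuple[float, float]) -> float:
    """Duration-weighted mean concentration over frames inside the window."""
    a, b = window
    mid = tac.midpoints
    sel = (mid >= a) & (mid <= b)
    if not sel.any():
        raise ValueError(f"no frames inside window {window}")
    d = tac.schedule.durations[sel]
    return float(np.sum(tac.values[sel] * d) / np.sum(d))


def suv(
    tac: TimeActivityCurve,
    dose_bq: float,
    weight_kg: float,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> StaticMeasure:
    """Standardized uptake value over the late static window.

    Concentration is kBq/mL; dose is total injected activity in Bq;
    weight in kg with the usual 1 g ~ 1 mL tissue convention, making SUV
    dimensionless.
    """
    if dose_bq <= 0 or weight_kg <= 0:
        raise ValueError("dose and weight must be positive")
    c_bq_per_ml = 1000.0 * _window_mean(tac, window)
    weight_g = weight_kg * 1000.0
    return StaticMeasure(
        kind="SUV",
        value=c_bq_per_ml / (dose_bq / weight_g),
        window=window,
        dose_bq=dose_bq,
        weight_kg=weight_kg,
    )


def fur(
    tac: TimeActivityCurve,
    input_fn: InputFunction,
    window: tuple[float, float] = DEFAULT_WINDOW,
    t_ref: str = "mid",
) -> StaticMeasure:
    """Fractional uptake ratio: window-mean uptake over the plasma integral.

    The plasma integral runs from 0 to T; T defaults to the window
    centre (``t_ref="mid"``), with the window end selectable
    (``t_ref="end"``).  Units are 1/min (mL/g/min with the density
    convention), directly comparable to Ki.
    """
    a, b = window
    t_upper = {"mid": 0.5 * (a + b), "end": b}.get(t_ref)
    if t_upper is None:
        raise ValueError("t_ref must be 'mid' or 'end'")
    denom = float(input_fn.integral(t_upper))
    if denom <= 0:
        raise ValueError("plasma integral must be positive")
    return StaticMeasure(
        kind="FUR", value=_window_mean(tac, window) / denom, window=window
    )


def patlak(
    tac: TimeActivityCurve,
    input_fn: InputFunction,
    t_star: float = 30.0,
) -> PatlakResult:
    """Patlak graphical analysis over frames with midpoint >= t*.

    Ordinary least squares of y = C_PET(T)/Cp(T) on x = int_0^T Cp/Cp(T);
    the slope is the net influx rate Ki for an irreversible tracer.
    """
    mid = tac.midpoints
    sel = mid >= t_star
    if sel.sum() < 2:
        raise ValueError("need >= 2 frames beyond t*")
    t = mid[sel]
    cp = input_fn(t)
    if np.any(cp <= 0):
        raise ValueError("Cp(T) must be positive beyond t*")
    x = input_fn.integral(t) / cp
    y = tac.values[sel] / cp
    if np.ptp(x) < 1e-12:
        raise ValueError("degenerate Patlak design: constant normalised time")
    res = stats.linregress(x, y)
    return PatlakResult(
        Ki=float(res.slope),
        intercept=float(res.intercept),
        t_star=t_star,
        n_points=int(sel.sum()),
        r_squared=float(res.rvalue**2),
    )
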