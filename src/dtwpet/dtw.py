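"""Dual-time-window (DTW) protocol: gap simulation and TAC completion.

The DTW protocol replaces a continuous 60-min dynamic scan with an early
acquisition (0..t1) and a late acquisition (t2..60).  The missing
mid-scan tissue activity is estimated by constrained fitting of a
3rd-degree rational function

    C_E(t) = (p3 t + p5 t^2 + p7 t^3) / (1 + p4 t + p6 t^2 + p8 t^3)

to the retained frames (p1 = 0 and p2 = 1 fixed; all other coefficients
nonnegative, which keeps the denominator >= 1 for t >= 0 and the curve
pole-free and nonnegative).  Estimated values fill the gap frames;
measured frames are never altered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .kinetics import (
    FitResult,
    FrameSchedule,
    InputFunction,
    TimeActivityCurve,
    fit_2t3k,
)
from .input_functions import HybridIFParams, hybrid_if_dtw

__all__ = [
    "DtwWindows",
    "RationalParams",
    "RationalFit",
    "truncate_to_dtw",
    "fit_rational3",
    "complete_tac",
    "mape",
    "percent_bias",
    "DtwPipelineResult",
    "run_dtw_pipeline",
]


@dataclass(frozen=True)
class DtwWindows:
    """Acquisition windows: early scan ends at t1, late scan runs t2..end."""

    t1: float
    t2: float
    end: float = 60.0

    def __post_init__(self) -> None:
        if not 0 < self.t1 < self.t2 < self.end:
            raise ValueError("need 0 < t1 < t2 < end")

    @property
    def label(self) -> str:
        return f"{self.t1:g}+{self.end - self.t2:g} min"


@dataclass(frozen=True)
class RationalParams:
    """Coefficients p3..p8 of the 3rd-degree rational completion curve."""

    p3: float
    p4: float
    p5: float
    p6: float
    p7: float
    p8: float

    def __post_init__(self) -> None:
        if min(self.p3, self.p4, self.p5, self.p6, self.p7, self.p8) < 0:
            raise ValueError("rational coefficients must be >= 0")

    def __call__(self, t: np.ndarray | float) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        num = self.p3 * t + self.p5 * t**2 + self.p7 * t**3
        den = 1.0 + self.p4 * t + self.p6 * t**2 + self.p8 * t**3
        return num / den

    def as_array(self) -> np.ndarray:
        return np.array([self.p3, self.p4, self.p5, self.p6, self.p7, self.p8])


@dataclass
class RationalFit:
    params: RationalParams
    rss: float
    converged: bool


def truncate_to_dtw(
    tac: TimeActivityCurve, windows: DtwWindows
) -> TimeActivityCurve:
    """Drop frames whose midpoint lies strictly inside (t1, t2).

    Frames straddling a window edge are kept or dropped by their
    midpoint, which makes the rule unambiguous; truncation is
    idempotent.
    """
    mid = tac.midpoints
    keep = ~((mid > windows.t1) & (mid < windows.t2))
    if not keep.any():
        raise ValueError("windows would remove every frame")
    return tac.subset(keep)


def fit_rational3(
    gapped_tac: TimeActivityCurve,
    weights: str = "uniform",
    n_starts: int = 5,
    fit_start_min: float = 3.0,
) -> RationalFit:
    """Fit the rational completion curve to the retained frames.

    Fitting targets the (midpoint, value) pairs of the retained frames
    with uniform weights by default (the gap frames are the prediction
    target, not the fit target).  Frames before ``fit_start_min`` are
    excluded: the first-pass bolus transit (spike-dip) is outside the
    shapes a positive-coefficient rational can represent, and forcing
    the fit through it distorts the interpolation across the gap, which
    is the sole purpose of the curve.  Rational fits are multimodal, so
    a small multi-start over log-spaced denominator scales is used;
    non-convergence returns the best-so-far flagged, never raises.
    """
    t = gapped_tac.midpoints
    y = gapped_tac.values
    late = t >= fit_start_min
    if late.sum() >= 8:
        t, y = t[late], y[late]
    if t.size < 8:
        raise ValueError("need >= 8 retained frames to constrain 6 coefficients")
    if weights == "uniform":
        w = np.ones_like(y)
    elif weights == "duration":
        w = gapped_tac.schedule.durations.astype(float)
    else:
        raise ValueError(f"unknown weight scheme {weights!r}")
    sw = np.sqrt(w / w.sum())

    if np.allclose(y, 0.0):
        return RationalFit(RationalParams(0, 0, 0, 0, 0, 0), 0.0, True)

    y_late = max(float(y[-1]), 1e-9)
    t_late = max(float(t[-1]), 1.0)

    def residuals(x: np.ndarray) -> np.ndarray:
        p = RationalParams(*np.clip(x, 0.0, None))
        return sw * (p(t) - y)

    best: tuple[float, np.ndarray, bool] | None = None
    any_ok = False
    for p4 in np.geomspace(0.03, 3.0, n_starts):
        # early rise ~ p3 t; asymptotic slope ~ p5/p4 matched to the plateau
        x0 = np.array([y_late * p4, p4, y_late * p4 / t_late, 1e-3, 1e-4, 1e-5])
        try:
            sol = least_squares(
                residuals, x0, bounds=(0.0, np.inf), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=2000,
            )
        except Exception:  # pragma: no cover
            continue
        rss = float(np.sum(sol.fun**2))
        any_ok = any_ok or bool(sol.success)
        if best is None or rss < best[0]:
            best = (rss, sol.x, bool(sol.success))
    if best is None:  # pragma: no cover
        return RationalFit(RationalParams(0, 0, 0, 0, 0, 0), np.inf, False)
    rss, x, _ = best
    return RationalFit(RationalParams(*np.clip(x, 0.0, None)), rss, any_ok)


def complete_tac(
    gapped_tac: TimeActivityCurve,
    params: RationalParams,
    full_schedule: FrameSchedule,
) -> TimeActivityCurve:
    """Fill the gap frames with the fitted curve at frame midpoints.

    Retained frames keep their measured values verbatim.
    """
    full_mid = full_schedule.midpoints
    gap_mid = gapped_tac.midpoints
    idx = np.searchsorted(full_mid, gap_mid)
    if (
        gap_mid.size == 0
        or np.any(idx >= full_mid.size)
        or not np.allclose(full_mid[np.clip(idx, 0, full_mid.size - 1)],
                           gap_mid, atol=1e-9)
    ):
        raise ValueError("gapped schedule is not a subset of the full schedule")
    measured = np.zeros(full_mid.size, dtype=bool)
    measured[idx] = True
    values = params(full_mid)
    values[measured] = gapped_tac.values
    return TimeActivityCurve(full_schedule, values)


def mape(
    estimated: TimeActivityCurve,
    measured: TimeActivityCurve,
    interval: tuple[float, float] | None = None,
) -> tuple[float, np.ndarray]:
    """Mean absolute percentage error over frames in ``interval``.

    Returns (MAPE in percent, per-frame absolute percentage errors).
    """
    if len(estimated.values) != len(measured.values) or not np.allclose(
        estimated.midpoints, measured.midpoints
    ):
        raise ValueError("estimated and measured TACs must share a schedule")
    mid = measured.midpoints
    sel = (
        np.ones_like(mid, dtype=bool)
        if interval is None
        else (mid > interval[0]) & (mid < interval[1])
    )
    if not sel.any():
        raise ValueError("no frames in the requested interval")
    cm = measured.values[sel]
    if np.any(cm == 0):
        raise ValueError("measured values must be nonzero for percentage error")
    per_frame = 100.0 * np.abs(estimated.values[sel] - cm) / np.abs(cm)
    return float(per_frame.mean()), per_frame


def percent_bias(k_ref: float, k_dtw: float) -> float:
    """Signed bias (K_ref - K_DTW)/K_ref * 100; positive = underestimation."""
    if k_ref == 0:
        raise ValueError("reference parameter must be nonzero")
    return 100.0 * (k_ref - k_dtw) / k_ref


@dataclass
class DtwPipelineResult:
    """End-to-end DTW quantification of one region."""

    windows: DtwWindows
    fit: FitResult
    rational: RationalFit
    hybrid_params: HybridIFParams
    completed: TimeActivityCurve
    hybrid_if: InputFunction
    gap_mape: float | None = None  # vs the hidden truth, when available


def run_dtw_pipeline(
    tissue_tac: TimeActivityCurve,
    idif_tac: TimeActivityCurve,
    pbidif: InputFunction,
    windows: DtwWindows,
    completed_weight: float = 0.02,
    **fit_kwargs,
) -> DtwPipelineResult:
    """Full DTW quantification: truncate, complete, bridge the IF, fit 2T3k.

    ``tissue_tac`` and ``idif_tac`` are full-schedule curves; the gap is
    simulated here by discarding mid-scan frames, exactly as when the
    protocol is emulated from an existing full dynamic scan.

    The completed frames are interpolations of the same measured data
    already present in the fit, not independent measurements; giving
    them full duration weight would double-count and propagate any
    interpolation bias into the kinetic parameters.  Their duration
    weights are therefore scaled by ``completed_weight`` (default 0.02,
    which gives the whole 45-min completed segment roughly the weight
    of one measured frame); pass 1.0 to weight them as measured data.
    """
    gapped = truncate_to_dtw(tissue_tac, windows)
    rational = fit_rational3(gapped)
    completed = complete_tac(gapped, rational.params, tissue_tac.schedule)

    gap_mape: float | None = None
    sel = (tissue_tac.midpoints > windows.t1) & (tissue_tac.midpoints < windows.t2)
    if sel.any() and np.all(tissue_tac.values[sel] != 0):
        gap_mape, _ = mape(completed, tissue_tac, interval=(windows.t1, windows.t2))

    idif_gapped = truncate_to_dtw(idif_tac, windows)
    early = idif_gapped.subset(idif_gapped.midpoints <= windows.t1)
    late = idif_gapped.subset(idif_gapped.midpoints >= windows.t2)
    hybrid, hp = hybrid_if_dtw(early, late, pbidif, windows.t1, windows.t2)

    if "weights" not in fit_kwargs:
        from .kinetics import frame_weights

        w = frame_weights(tissue_tac.schedule).copy()
        mid = tissue_tac.schedule.midpoints
        w[(mid > windows.t1) & (mid < windows.t2)] *= completed_weight
        fit_kwargs["weights"] = w
    fit = fit_2t3k(completed, hybrid, **fit_kwargs)
    return DtwPipelineResult(
        windows=windows,
        fit=fit,
        rational=rational,
        hybrid_params=hp,
        completed=completed,
        hybrid_if=hybrid,
        gap_mape=gap_mape,
    )
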