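"""Image-derived and hybrid input functions for dynamic FDG PET.

A subject's blood curve is measured from a vascular ROI (image-derived
input function, IDIF).  In a dual-time-window acquisition the middle of
the scan is missing, so the unscanned interval is bridged with a
population-based IDIF (PB-IDIF) rescaled to match the subject at the
window edges::

    Cp(t) = C_image(t)                      0 <= t < t1
          = mu * exp(-gamma (t - t1)) * Cp0(t)   t1 <= t < t2
          = C_image(t)                      t2 <= t <= 60

The scaling factors are fixed by continuity at both joins:
mu = C_image(t1)/Cp0(t1) and gamma = ln(mu Cp0(t2)/C_image(t2))/(t2-t1).

For single-static-scan measures (FUR, Patlak) the PB-IDIF is instead
scaled by a single factor alpha matching the late-window AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetics import (
    FitResult,
    FrameSchedule,
    InputFunction,
    TimeActivityCurve,
    fit_2t3k,
)

__all__ = [
    "HybridIFParams",
    "DelayResult",
    "extract_roi_tac",
    "build_pb_idif",
    "hybrid_if_dtw",
    "scale_pbif_static",
    "correct_delay",
]


@dataclass(frozen=True)
class HybridIFParams:
    """Scaling factors of a hybrid input function."""

    mu: float  # amplitude match at t1 (dimensionless)
    gamma: float  # exponential shape correction (1/min)
    alpha: float  # static AUC scale (dimensionless); 1 for the DTW bridge
    t1: float  # end of early segment (min)
    t2: float  # start of late segment (min)

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.alpha <= 0:
            raise ValueError("mu and alpha must be > 0")
        if not 0 < self.t1 < self.t2 <= 60:
            raise ValueError("need 0 < t1 < t2 <= 60 min")


def extract_roi_tac(image4d, mask: np.ndarray) -> TimeActivityCurve:
    """Per-frame mean activity over the voxels of a 3-D mask.

    ``image4d`` is a :class:`~dtwpet.parametric.DynamicImage`.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image4d.data.shape[:3]:
        raise ValueError("mask and image grids differ")
    if not mask.any():
        raise ValueError("empty ROI mask")
    means = image4d.data[mask].mean(axis=0)
    return TimeActivityCurve(image4d.schedule, means)


def _tac_interpolant(tac: TimeActivityCurve) -> tuple[np.ndarray, np.ndarray]:
    return tac.midpoints, tac.values


def build_pb_idif(
    tacs: list[TimeActivityCurve],
    doses_mbq: np.ndarray,
    weights_kg: np.ndarray,
    grid: np.ndarray | None = None,
) -> InputFunction:
    """Population-based IDIF: dose-per-weight-normalised subject IDIFs averaged.

    Each curve is divided by its subject's injected dose per body weight
    (MBq/kg, the SUV convention), resampled to a common grid, and
    averaged.  The result is a shape template: downstream hybrid
    assembly rescales it to the individual subject, so the normalised
    units cancel.

    Parameters
    ----------
    grid : common time grid (minutes).  Defaults to the frame midpoints
        of the first subject's schedule, avoiding resampling artifacts
        when all subjects share the standard schedule.
    """
    if len(tacs) < 2:
        raise ValueError("population input function needs >= 2 subjects")
    doses = np.asarray(doses_mbq, dtype=float)
    weights = np.asarray(weights_kg, dtype=float)
    if doses.shape != (len(tacs),) or weights.shape != (len(tacs),):
        raise ValueError("one dose and one weight per subject required")
    if np.any(doses <= 0) or np.any(weights <= 0):
        raise ValueError("doses and weights must be positive")
    if grid is None:
        grid = tacs[0].midpoints
    resampled = np.empty((len(tacs), grid.size))
    for i, tac in enumerate(tacs):
        t, v = _tac_interpolant(tac)
        resampled[i] = np.interp(grid, t, v) / (doses[i] / weights[i])
    return InputFunction(grid, resampled.mean(axis=0))


def hybrid_if_dtw(
    idif_early: TimeActivityCurve,
    idif_late: TimeActivityCurve,
    pbidif: InputFunction,
    t1: float,
    t2: float,
    bridge_step_min: float = 0.25,
) -> tuple[InputFunction, HybridIFParams]:
    """Assemble the dual-time-window hybrid input function.

    The measured early and late IDIF segments are kept verbatim; the gap
    (t1, t2) carries the population curve rescaled by mu and bent by an
    exponential so that the assembly is continuous at both joins.
    """
    if not 0 < t1 < t2 <= 60:
        raise ValueError("need 0 < t1 < t2 <= 60 min")
    if len(idif_early.values) == 0 or len(idif_late.values) == 0:
        raise ValueError("both measured IDIF segments must be nonempty")

    te, ve = _tac_interpolant(idif_early)
    tl, vl = _tac_interpolant(idif_late)
    # join where data exists: the last early and first late sample times
    ta = float(te[te <= t1 + 1e-9].max(initial=te.max()))
    tb = float(tl[tl >= t2 - 1e-9].min(initial=tl.min()))
    c_img_ta = float(np.interp(ta, te, ve))
    c_img_tb = float(np.interp(tb, tl, vl))
    cp0_ta = float(pbidif(ta))
    cp0_tb = float(pbidif(tb))
    if cp0_ta <= 0 or cp0_tb <= 0:
        raise ValueError("population curve must be positive at the joins")
    if c_img_ta <= 0 or c_img_tb <= 0:
        raise ValueError("measured IDIF must be positive at the joins")

    mu = c_img_ta / cp0_ta
    gamma = np.log(mu * cp0_tb / c_img_tb) / (tb - ta)
    params = HybridIFParams(mu=mu, gamma=float(gamma), alpha=1.0, t1=ta, t2=tb)

    bridge_t = np.union1d(
        pbidif.times[(pbidif.times > ta) & (pbidif.times < tb)],
        np.arange(ta, tb, bridge_step_min),
    )
    bridge_t = bridge_t[(bridge_t > ta) & (bridge_t < tb)]
    bridge_v = mu * np.exp(-gamma * (bridge_t - ta)) * pbidif(bridge_t)

    times = np.concatenate([te[te <= ta], bridge_t, tl[tl >= tb]])
    vals = np.concatenate([ve[te <= ta], bridge_v, vl[tl >= tb]])
    order = np.argsort(times)
    times, vals = times[order], vals[order]
    keep = np.concatenate([[True], np.diff(times) > 1e-9])
    return InputFunction(times[keep], vals[keep]), params


def scale_pbif_static(
    idif_late: TimeActivityCurve,
    pbidif: InputFunction,
    window: tuple[float, float] = (50.0, 60.0),
) -> tuple[InputFunction, HybridIFParams]:
    """Scale the PB-IDIF by the measured late-window AUC (single static scan).

    alpha = AUC_image(window) / AUC_pbidif(window); the returned curve is
    alpha*Cp0 before the window and the measured data inside it.  Both
    AUCs run over the part of the window the measured samples cover, so
    the ratio is unbiased by extrapolation conventions at the edges.
    """
    a, b = window
    tl, vl = _tac_interpolant(idif_late)
    if tl.min() > a + (b - a) / 2 or tl.max() < a:
        raise ValueError(f"late segment must cover the window {window}")
    lo = max(a, float(tl.min()))
    hi = min(b, float(tl.max()))
    grid = np.union1d(np.linspace(lo, hi, 41), tl[(tl >= lo) & (tl <= hi)])
    auc_img = float(np.trapezoid(np.interp(grid, tl, vl), grid))
    auc_pb = pbidif.auc(lo, hi)
    if auc_pb <= 0:
        raise ValueError("population curve has zero AUC in the window")
    alpha = auc_img / auc_pb
    params = HybridIFParams(mu=1.0, gamma=0.0, alpha=alpha, t1=a, t2=b)

    pre = pbidif.times[pbidif.times < a]
    times = np.concatenate([pre, [a], tl[tl > a]])
    vals = np.concatenate(
        [alpha * pbidif(pre), [float(np.interp(a, tl, vl))], vl[tl > a]]
    )
    keep = np.concatenate([[True], np.diff(times) > 1e-9])
    return InputFunction(times[keep], vals[keep]), params


@dataclass
class DelayResult:
    """Outcome of the input-function delay grid search."""

    delay_s: float
    shifts_s: np.ndarray
    objectives: np.ndarray
    best_fit: FitResult


def correct_delay(
    tac: TimeActivityCurve,
    input_fn: InputFunction,
    range_s: float = 60.0,
    step_s: float = 1.0,
    **fit_kwargs,
) -> DelayResult:
    """Estimate the blood-to-tissue delay by exhaustive shift search.

    The input function is shifted on a grid within +/- ``range_s``
    seconds; a 2T3k model is fitted at every shift and the shift with
    the lowest weighted residual sum of squares wins.
    """
    n = int(round(range_s / step_s))
    if abs(n * step_s - range_s) > 1e-9:
        raise ValueError("step must divide the search range")
    shifts = np.arange(-n, n + 1) * step_s
    objectives = np.empty(shifts.size)
    fits: list[FitResult] = []
    for j, s in enumerate(shifts):
        fit = fit_2t3k(tac, input_fn.shifted(s / 60.0), **fit_kwargs)
        fit.delay_min = s / 60.0
        objectives[j] = fit.weighted_rss
        fits.append(fit)
    best = int(np.argmin(objectives))
    return DelayResult(
        delay_s=float(shifts[best]),
        shifts_s=shifts,
        objectives=objectives,
        best_fit=fits[best],
    )
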