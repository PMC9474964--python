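"""Voxel-wise parametric imaging via the linearised 2T3k model.

Integrating the irreversible two-tissue ODE system twice from t=0 turns
the nonlinear estimation problem into a linear one::

    C_T(t) = P1 Cp(t) + P2 int Cp + P3 iint Cp + P4 int C_T

with P1 = Vb, P2 = (1-Vb) K1 + theta Vb, P3 = (1-Vb) K1 k3,
P4 = -theta, theta = k2 + k3 (the reversible double-integral term P5
vanishes when k4 = 0).  Negating the int C_T column makes every unknown
nonnegative, so each voxel is a small Lawson-Hanson NNLS solve — fast
enough for whole-body multiparametric maps.  Micro-parameters are then
recovered by inverting the mapping:

    Vb = P1,  theta = theta4,  K1 = (P2 - P1 theta4)/(1 - P1),
    k3 = P3 / ((1 - P1) K1),  k2 = theta4 - k3,
    Ki = P3 / ((1 - P1) theta4).

Degenerate voxels (empty, blood-only, non-physiologic coefficient
combinations) yield zeroed parameters with a flag rather than NaNs, so
map post-processing never trips over isolated voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import nnls

from .kinetics import (
    FrameSchedule,
    InputFunction,
    KineticParams,
    TimeActivityCurve,
    net_influx_rate,
)

__all__ = [
    "DynamicImage",
    "LinearizedCoeffs",
    "ParametricMaps",
    "linearized_basis",
    "plasma_basis",
    "tissue_integrals",
    "nnls_2t3k_voxel",
    "fit_parametric_images",
    "roi_cov",
]


@dataclass
class DynamicImage:
    """4-D dynamic PET volume: (x, y, z, frame) activity in kBq/mL."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    schedule: FrameSchedule
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("dynamic image must be 4-D (x, y, z, frame)")
        if self.data.shape[3] != len(self.schedule):
            raise ValueError("frame axis must match the schedule length")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image values must be finite")
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size_mm) + [1.0])


@dataclass(frozen=True)
class LinearizedCoeffs:
    """Coefficients of the linearised model; P4 = -theta4 <= 0, P5 = 0."""

    P1: float
    P2: float
    P3: float
    P4: float
    P5: float = 0.0

    @property
    def theta4(self) -> float:
        return -self.P4


@dataclass
class ParametricMaps:
    """Voxel-wise kinetic parameter volumes on the source spatial grid."""

    K1: np.ndarray
    k2: np.ndarray
    k3: np.ndarray
    Vb: np.ndarray
    Ki: np.ndarray
    flags: np.ndarray  # True where the voxel solve was degenerate
    method: str = "nnls_2t3k"

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"K1": self.K1, "k2": self.k2, "k3": self.k3,
                "Vb": self.Vb, "Ki": self.Ki}


def plasma_basis(
    input_fn: InputFunction, midpoints: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(Cp, int Cp, iint Cp) at the frame midpoints.

    The single integral is exact for the piecewise-linear input; the
    double integral is accumulated on a refined grid.
    """
    midpoints = np.asarray(midpoints, dtype=float)
    fine = np.union1d(
        np.union1d(input_fn.times, midpoints),
        np.linspace(0.0, float(midpoints.max()), 1201),
    )
    fine = fine[fine <= midpoints.max() + 1e-12]
    single = input_fn.integral(fine)
    double = cumulative_trapezoid(single, fine, initial=0.0)
    return (
        input_fn(midpoints),
        input_fn.integral(midpoints),
        np.interp(midpoints, fine, double),
    )


def tissue_integrals(
    values: np.ndarray, midpoints: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(int C_T, iint C_T) at midpoints by cumulative trapezoid from t=0.

    The curve is anchored at (0, 0): there is no tissue activity before
    injection.  ``values`` may be (n,) or (m, n) for batched voxels.
    """
    was_1d = np.asarray(values).ndim == 1
    values = np.atleast_2d(np.asarray(values, dtype=float))
    t = np.concatenate([[0.0], midpoints])
    v = np.concatenate([np.zeros((values.shape[0], 1)), values], axis=1)
    single = cumulative_trapezoid(v, t, axis=1, initial=0.0)[:, 1:]
    s0 = np.concatenate([np.zeros((values.shape[0], 1)), single], axis=1)
    double = cumulative_trapezoid(s0, t, axis=1, initial=0.0)[:, 1:]
    if was_1d:
        return single[0], double[0]
    return single, double


def linearized_basis(
    tac: TimeActivityCurve, input_fn: InputFunction
) -> dict[str, np.ndarray]:
    """All five design terms of the linearised model at frame midpoints."""
    mid = tac.midpoints
    cp, icp, iicp = plasma_basis(input_fn, mid)
    ict, iict = tissue_integrals(tac.values, mid)
    return {"cp": cp, "int_cp": icp, "iint_cp": iicp,
            "int_ct": ict, "iint_ct": iict}


def _backmap(P1: float, P2: float, P3: float, theta4: float
             ) -> tuple[KineticParams, bool]:
    """Invert (P1, P2, P3, theta4) -> (K1, k2, k3, Vb); flag degeneracies."""
    zero = KineticParams(0.0, 0.0, 0.0, min(max(P1, 0.0), 1.0))
    if P1 >= 1.0:
        return KineticParams(0.0, 0.0, 0.0, 1.0), True
    u = 1.0 - P1
    K1 = (P2 - P1 * theta4) / u
    if K1 <= 0.0:
        return zero, not (P2 == 0.0 and P3 == 0.0)
    if theta4 <= 0.0:
        # no efflux or trapping beyond delivery: k2 = k3 = 0, Ki = 0
        return KineticParams(K1, 0.0, 0.0, P1), P3 > 0.0
    k3 = P3 / (u * K1)
    flagged = False
    if k3 > theta4:
        k3, flagged = theta4, True  # clip: k2 would be negative
    return KineticParams(K1, theta4 - k3, k3, P1), flagged


def nnls_2t3k_voxel(
    basis: dict[str, np.ndarray] | tuple[np.ndarray, ...],
    tac_values: np.ndarray,
) -> tuple[LinearizedCoeffs, KineticParams, bool]:
    """Solve one voxel of the linearised irreversible model by NNLS.

    Returns (coefficients, micro-parameters, degenerate-flag).  The
    int C_T column is negated so that all NNLS unknowns, including
    theta4 = -P4, are nonnegative.
    """
    if isinstance(basis, dict):
        cp, icp, iicp = basis["cp"], basis["int_cp"], basis["iint_cp"]
        ict = basis.get("int_ct")
        if ict is None:
            ict, _ = tissue_integrals(tac_values, None)  # pragma: no cover
    else:
        cp, icp, iicp, ict = basis
    y = np.asarray(tac_values, dtype=float)
    A = np.column_stack([cp, icp, iicp, -ict])
    if np.allclose(y, 0.0):
        coeffs = LinearizedCoeffs(0.0, 0.0, 0.0, 0.0)
        return coeffs, KineticParams(0.0, 0.0, 0.0, 0.0), True
    x, _ = nnls(A, y)
    P1, P2, P3, theta4 = (float(v) for v in x)
    coeffs = LinearizedCoeffs(P1, P2, P3, -theta4)
    params, flagged = _backmap(min(P1, 1.0), P2, P3, theta4)
    return coeffs, params, flagged


def fit_parametric_images(
    image4d: DynamicImage,
    input_fn: InputFunction,
    method: str = "nnls_2t3k",
    mask: np.ndarray | None = None,
    t_star: float = 30.0,
) -> ParametricMaps:
    """Voxel-wise kinetic maps from a 4-D image.

    ``nnls_2t3k`` produces K1/k2/k3/Vb/Ki maps from the full dynamic
    data; ``patlak`` produces a Ki (slope) map from frames with midpoint
    >= t* (K1/k2/k3/Vb maps are zero in that mode).
    """
    sched = image4d.schedule
    shape = image4d.data.shape[:3]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise ValueError("mask and image grids differ")
    mid = sched.midpoints
    vox = image4d.data[mask]  # (m, n_frames)

    maps = {k: np.zeros(shape) for k in ("K1", "k2", "k3", "Vb", "Ki")}
    flags = np.zeros(shape, dtype=bool)

    if method == "patlak":
        sel = mid >= t_star
        if sel.sum() < 2:
            raise ValueError("need >= 2 frames beyond t*")
        cp = input_fn(mid[sel])
        if np.any(cp <= 0):
            raise ValueError("Cp(T) must be positive beyond t*")
        x = input_fn.integral(mid[sel]) / cp
        y = vox[:, sel] / cp
        xc = x - x.mean()
        denom = float(np.sum(xc**2))
        if denom < 1e-12:
            raise ValueError("degenerate Patlak design")
        slope = (y - y.mean(axis=1, keepdims=True)) @ xc / denom
        ki = np.zeros(shape)
        ki[mask] = slope
        return ParametricMaps(
            K1=maps["K1"], k2=maps["k2"], k3=maps["k3"], Vb=maps["Vb"],
            Ki=ki, flags=flags, method="patlak",
        )

    if method != "nnls_2t3k":
        raise ValueError("method must be 'nnls_2t3k' or 'patlak'")

    cp, icp, iicp = plasma_basis(input_fn, mid)
    ict_all, _ = tissue_integrals(vox, mid)
    out = np.zeros((vox.shape[0], 5))
    vflags = np.zeros(vox.shape[0], dtype=bool)
    for i in range(vox.shape[0]):
        _, p, fl = nnls_2t3k_voxel((cp, icp, iicp, ict_all[i]), vox[i])
        out[i] = [p.K1, p.k2, p.k3, p.Vb, p.Ki]
        vflags[i] = fl
    for j, k in enumerate(("K1", "k2", "k3", "Vb", "Ki")):
        maps[k][mask] = out[:, j]
    flags[mask] = vflags
    return ParametricMaps(flags=flags, method="nnls_2t3k", **maps)


def roi_cov(volume: np.ndarray, mask: np.ndarray, ddof: int = 0) -> float:
    """Coefficient of variation (SD/mean) over the masked voxels.

    Population SD (ddof=0) by default; sample SD selectable.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty ROI mask")
    vals = np.asarray(volume, dtype=float)[mask]
    mean = vals.mean()
    if mean == 0:
        raise ValueError("ROI mean is zero; CoV undefined")
    return float(vals.std(ddof=ddof) / mean)
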