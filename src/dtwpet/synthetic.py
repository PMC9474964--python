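"""Synthetic FDG data: arterial input functions, tissue TACs, virtual
subjects, and small 4-D phantoms.

The arterial curve follows the classic tri-exponential model of an FDG
bolus::

    Cp(t) = (A1 (t-td) - A2 - A3) e^{l1 (t-td)} + A2 e^{l2 (t-td)} + A3 e^{l3 (t-td)}

for t >= td (0 before), with a sharp delivery peak and a slowly decaying
tail.  Tissue curves are generated through the exact irreversible 2T3k
forward model and frame-averaged on the standard 66-frame schedule.
Measurement noise emulates count-limited frame variance,
sigma_i = Sc * sqrt(C(t_i)/dt_i), Gaussian and independent per frame,
clipped at zero.  Population variability enters as log-normal
multipliers on the bolus amplitudes.

Every generator is seed-deterministic: the same seed reproduces the
same cohort bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .kinetics import (
    FrameSchedule,
    InputFunction,
    KineticParams,
    TimeActivityCurve,
    build_frame_schedule,
    frame_average,
    model_tac,
)
from .parametric import DynamicImage

__all__ = [
    "FengIFParams",
    "TissuePrior",
    "NoiseModel",
    "DEFAULT_NOISE_SCALE",
    "ROI_NOISE_SCALE",
    "Subject",
    "feng_input",
    "default_if_grid",
    "simulate_subject",
    "simulate_cohort",
    "simulate_phantom",
    "TISSUE_PRIORS",
    "DEFAULT_FENG",
]


@dataclass(frozen=True)
class FengIFParams:
    """Tri-exponential arterial bolus model parameters."""

    A1: float = 851.1  # kBq/mL/min
    A2: float = 21.9  # kBq/mL
    A3: float = 20.8  # kBq/mL
    lam1: float = -4.134  # 1/min
    lam2: float = -0.1191  # 1/min
    lam3: float = -0.0104  # 1/min
    t_delay: float = 0.5  # min

    def __post_init__(self) -> None:
        if not self.lam1 < self.lam2 <= self.lam3 < 0:
            raise ValueError("need lam1 < lam2 <= lam3 < 0")
        if self.t_delay < 0:
            raise ValueError("delay must be >= 0")

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        tt = t - self.t_delay
        c = (
            (self.A1 * tt - self.A2 - self.A3) * np.exp(self.lam1 * tt)
            + self.A2 * np.exp(self.lam2 * tt)
            + self.A3 * np.exp(self.lam3 * tt)
        )
        return np.where(tt >= 0, c, 0.0)


DEFAULT_FENG = FengIFParams()


@dataclass(frozen=True)
class TissuePrior:
    """Uniform parameter ranges for a named tissue class."""

    name: str
    K1: tuple[float, float]
    k2: tuple[float, float]
    k3: tuple[float, float]
    Vb: tuple[float, float]

    def draw(self, rng: np.random.Generator) -> KineticParams:
        return KineticParams(
            K1=rng.uniform(*self.K1),
            k2=rng.uniform(*self.k2),
            k3=rng.uniform(*self.k3),
            Vb=rng.uniform(*self.Vb),
        )

    def midpoint(self) -> KineticParams:
        return KineticParams(
            K1=np.mean(self.K1), k2=np.mean(self.k2),
            k3=np.mean(self.k3), Vb=np.mean(self.Vb),
        )


TISSUE_PRIORS: dict[str, TissuePrior] = {
    "cortex": TissuePrior("cortex", (0.08, 0.12), (0.10, 0.16), (0.04, 0.08), (0.03, 0.06)),
    "muscle": TissuePrior("muscle", (0.02, 0.04), (0.15, 0.30), (0.01, 0.03), (0.01, 0.04)),
    "tumor": TissuePrior("tumor", (0.10, 0.60), (0.20, 0.60), (0.05, 0.15), (0.04, 0.12)),
}


#: Default count-noise scale: puts late-frame relative SD at ~6% (cortex,
#: tumor) to ~14% (cold muscle), the regime of total-body reconstructions.
#: This is voxel/image-level noise, appropriate for phantom voxels.
DEFAULT_NOISE_SCALE = 0.6

#: ROI-level noise scale.  Regional TACs average many voxels, which
#: shrinks frame noise by ~sqrt(N); a modest 3-D ROI of ~64 voxels gives
#: image-level noise / 8.  Used by cohort ROI-quantification studies.
ROI_NOISE_SCALE = DEFAULT_NOISE_SCALE / 8.0


@dataclass(frozen=True)
class NoiseModel:
    """Count-variance-like frame noise: sigma_i = scale*sqrt(C_i/dt_i)."""

    scale: float = DEFAULT_NOISE_SCALE

    def __post_init__(self) -> None:
        if self.scale < 0:
            raise ValueError("noise scale must be >= 0")

    def sigma(self, values: np.ndarray, durations: np.ndarray) -> np.ndarray:
        return self.scale * np.sqrt(np.clip(values, 0.0, None) / durations)

    def apply(
        self, tac: TimeActivityCurve, rng: np.random.Generator
    ) -> TimeActivityCurve:
        if self.scale == 0:
            return tac
        sig = self.sigma(tac.values, tac.schedule.durations)
        noisy = tac.values + rng.normal(0.0, 1.0, tac.values.shape) * sig
        return TimeActivityCurve(tac.schedule, np.clip(noisy, 0.0, None))


def default_if_grid() -> np.ndarray:
    """Knot grid for piecewise-linear input functions: dense near the peak."""
    return np.unique(np.concatenate([
        np.arange(0.0, 3.0, 0.02),
        np.arange(3.0, 10.0, 0.1),
        np.arange(10.0, 60.25, 0.25),
        [60.0],
    ]))


def feng_input(
    params: FengIFParams = DEFAULT_FENG, grid: np.ndarray | None = None
) -> InputFunction:
    """Evaluate the bolus model on a grid and wrap it as an InputFunction."""
    if grid is None:
        grid = default_if_grid()
    vals = params(grid)
    if vals.min() < -1e-6 * max(vals.max(), 1.0):
        raise ValueError("input model goes negative beyond clipping tolerance")
    return InputFunction(grid, np.clip(vals, 0.0, None))


@dataclass
class Subject:
    """One virtual subject: blood and tissue curves plus ground truth."""

    input_fn: InputFunction  # true continuous-time blood curve
    idif_tac: TimeActivityCurve  # frame-sampled (optionally noisy) blood TAC
    tissue_tacs: dict[str, TimeActivityCurve]
    truth: dict[str, KineticParams]
    dose_mbq: float
    weight_kg: float
    if_params: FengIFParams


def _jittered_if(
    base: FengIFParams,
    rng: np.random.Generator,
    jitter_cv: float,
    amplitude_scale: float,
) -> FengIFParams:
    if jitter_cv > 0:
        sigma = np.sqrt(np.log1p(jitter_cv**2))
        mult = rng.lognormal(-0.5 * sigma**2, sigma, size=3)
    else:
        mult = np.ones(3)
    return replace(
        base,
        A1=base.A1 * amplitude_scale * mult[0],
        A2=base.A2 * amplitude_scale * mult[1],
        A3=base.A3 * amplitude_scale * mult[2],
    )


def simulate_subject(
    rng: np.random.Generator | int,
    schedule: FrameSchedule | None = None,
    priors: dict[str, TissuePrior] | None = None,
    base_if: FengIFParams = DEFAULT_FENG,
    jitter_cv: float = 0.15,
    noise: NoiseModel = NoiseModel(0.0),
    dose_mean_mbq: float = 230.0,
    dose_sd_mbq: float = 35.0,
    weight_mean_kg: float = 62.0,
    weight_sd_kg: float = 9.0,
) -> Subject:
    """Draw one virtual subject.

    The bolus amplitude scales with the subject's injected dose per
    body weight (tracer concentration tracks delivered activity per
    distribution volume); log-normal jitter on top creates the
    between-subject shape variability that makes a population curve an
    imperfect surrogate for the individual one.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    if schedule is None:
        schedule = build_frame_schedule()
    if priors is None:
        priors = TISSUE_PRIORS

    dose = float(np.clip(rng.normal(dose_mean_mbq, dose_sd_mbq), 100.0, 450.0))
    weight = float(np.clip(rng.normal(weight_mean_kg, weight_sd_kg), 35.0, 120.0))
    amp = (dose / weight) / (dose_mean_mbq / weight_mean_kg)
    ifp = _jittered_if(base_if, rng, jitter_cv, amp)
    input_fn = feng_input(ifp)

    idif = noise.apply(frame_average(input_fn, schedule), rng)
    truth: dict[str, KineticParams] = {}
    tacs: dict[str, TimeActivityCurve] = {}
    for name, prior in priors.items():
        p = prior.draw(rng)
        truth[name] = p
        tacs[name] = noise.apply(model_tac(input_fn, p, schedule), rng)
    return Subject(
        input_fn=input_fn,
        idif_tac=idif,
        tissue_tacs=tacs,
        truth=truth,
        dose_mbq=dose,
        weight_kg=weight,
        if_params=ifp,
    )


def simulate_cohort(
    n_subjects: int, seed: int, **subject_kwargs
) -> list[Subject]:
    """Seed-deterministic cohort of virtual subjects."""
    rng = np.random.default_rng(seed)
    return [simulate_subject(rng, **subject_kwargs) for _ in range(n_subjects)]


def simulate_phantom(
    rng: np.random.Generator | int,
    region_spec: dict[str, tuple[tuple[slice, slice, slice], KineticParams | None]]
    | None = None,
    dims: tuple[int, int, int] = (24, 24, 8),
    schedule: FrameSchedule | None = None,
    noise: NoiseModel = NoiseModel(0.0),
    base_if: FengIFParams = DEFAULT_FENG,
) -> tuple[DynamicImage, dict[str, np.ndarray], dict[str, KineticParams | None]]:
    """Small 4-D phantom with homogeneous kinetic regions.

    ``region_spec`` maps region name -> (box slices, KineticParams); a
    ``None`` parameter set marks the blood-pool region, which carries
    the frame-averaged input function itself.  Voxels outside every
    region stay zero.  Noise is i.i.d. per voxel and frame.

    Returns (image, masks, truth) where truth[name] is the generating
    parameter set (None for blood).
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    if schedule is None:
        schedule = build_frame_schedule()
    if region_spec is None:
        half_x, half_y = dims[0] // 2, dims[1] // 2
        zs = slice(0, dims[2])
        region_spec = {
            "blood": ((slice(0, half_x), slice(0, half_y), zs), None),
            "cortex": ((slice(half_x, dims[0]), slice(0, half_y), zs),
                       TISSUE_PRIORS["cortex"].midpoint()),
            "muscle": ((slice(0, half_x), slice(half_y, dims[1]), zs),
                       TISSUE_PRIORS["muscle"].midpoint()),
            "tumor": ((slice(half_x, dims[0]), slice(half_y, dims[1]), zs),
                      TISSUE_PRIORS["tumor"].midpoint()),
        }

    input_fn = feng_input(base_if)
    data = np.zeros(dims + (len(schedule),))
    occupied = np.zeros(dims, dtype=bool)
    masks: dict[str, np.ndarray] = {}
    truth: dict[str, KineticParams | None] = {}
    for name, (box, params) in region_spec.items():
        mask = np.zeros(dims, dtype=bool)
        mask[box] = True
        if (mask & occupied).any():
            raise ValueError(f"region {name!r} overlaps another region")
        occupied |= mask
        if params is None:
            clean = frame_average(input_fn, schedule).values
        else:
            clean = model_tac(input_fn, params, schedule).values
        n_vox = int(mask.sum())
        block = np.tile(clean, (n_vox, 1))
        if noise.scale > 0:
            sig = noise.sigma(clean, schedule.durations)
            block = np.clip(
                block + rng.normal(0.0, 1.0, block.shape) * sig, 0.0, None
            )
        data[mask] = block
        masks[name] = mask
        truth[name] = params
    image = DynamicImage(data, (3.0, 3.0, 3.0), schedule)
    return image, masks, truth
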