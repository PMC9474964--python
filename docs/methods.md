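# Methods

## Scope and model

`dtwpet` quantifies dynamic ¹⁸F-FDG PET with the irreversible
two-tissue compartment model (2T3k: K₁, k₂, k₃ free, k₄ = 0, fractional
blood volume V_b), and implements a dual-time-window (DTW) protocol in
which the middle of a 60-minute dynamic acquisition is not scanned:
tissue curves are completed by constrained rational-function fitting and
the blood curve is bridged with a rescaled population input function.
Decay correction, reconstruction, attenuation/scatter handling, motion
compensation, dispersion and blood-to-plasma conversion are out of
scope: inputs are assumed to be fully corrected activity-concentration
images or regional TACs, with whole-blood activity standing in for
plasma.

Internal time unit is minutes (rates are min⁻¹); I/O accepts seconds and
converts. Activity concentrations are kBq/mL.

## Forward model and its evaluation

With θ = k₂ + k₃, the solution of the 2T3k system is

    C₁+C₂ = K_i ∫₀ᵗ C_p + (K₁k₂/θ) · (e^{−θt} ⊛ C_p)(t),   K_i = K₁k₃/θ,
    C_PET = V_b C_p + (1−V_b)(C₁+C₂),

with the θ = 0 limit C₁+C₂ = K₁∫C_p. Input functions are
piecewise-linear curves; the exponential convolution is evaluated
analytically per linear segment (block-rescaled cumulative recurrence,
stable for θ·t up to the optimizer bounds θ ≤ 10 min⁻¹ over 60 min), and
∫C_p is the exact trapezoid. There is therefore no ODE or FFT grid
error in the forward model; the unit tests verify it against an
independent stiff ODE integration to 0.1%.

Frame values are frame *averages* of the continuous model by sub-frame
quadrature (default 8 subdivisions; midpoint sampling selectable for
voxel loops). Frame weights ω_i in the χ² objective default to frame
duration normalised to unit sum — a proxy for count-variance weighting
on decay-corrected data — with uniform weights selectable.

## Nonlinear fitting

`fit_2t3k` minimises Σ ω_i (C_PET(t_i) − C_t(t_i; p))² with bounded
trust-region least squares from four fixed starting points spanning the
physiologic box K₁, k₂, k₃ ∈ [0, 5], V_b ∈ [0, 1]; the best start by
weighted RSS wins. All-zero TACs short-circuit to zero parameters;
optimizer failures return the best-so-far flagged rather than raising,
so region and voxel loops survive degenerate inputs.

Delay between the blood and tissue curves is estimated by exhaustive
grid search (default ±60 s in 1-s steps, both configurable): the input
function is shifted, a full fit is run at every shift, and the shift
with the lowest weighted RSS wins.

## DTW protocol

Truncation removes frames whose midpoint lies strictly inside (t₁, t₂);
the supported configurations are (10, 55), (10, 50) and (10, 40) min,
i.e. 10 + 5, 10 + 10 and 10 + 20 min of scanning. On the standard
66-frame schedule (24×5 s, 6×10 s, 6×30 s, 6×60 s, 24×120 s — note the
early blocks sum to 12 min) the (10, 55) configuration retains 43
frames.

The gap is completed with the 3rd-degree rational curve

    C_E(t) = (p₃t + p₅t² + p₇t³) / (1 + p₄t + p₆t² + p₈t³),

all coefficients ≥ 0, which pins C_E(0) = 0, keeps the denominator ≥ 1
for t ≥ 0 (no poles), and makes the completed values finite and
nonnegative. The fit targets the (midpoint, value) pairs of retained
frames with uniform weights and a 5-point multi-start over log-spaced
denominator scales. Two design choices matter here:

* **Fit domain.** Frames with midpoint < 3 min are excluded by default
  (`fit_start_min`). The first-pass bolus transit is a spike-dip shape
  that a positive-coefficient rational cannot represent; forcing the fit
  through it distorts the interpolation across the gap — on noise-free
  tissue curves the gap MAPE drops from 5–7% to ≤ 1.7% across all three
  window configurations when the transit is excluded. The completion's
  only purpose is the bridge, so the bridge accuracy wins.
* **Weight of completed frames in the subsequent kinetic fit.**
  Completed frames are interpolations of measured data already present
  in the fit, not independent measurements. `run_dtw_pipeline` scales
  their duration weights by 0.02 (the whole 45-min completed segment
  then carries roughly the weight of one measured frame). At full
  weight, interpolation bias propagates into the parameters: on a
  50-subject noise-free cohort the worst-case K_i error is 7.2% (K₁:
  11.9%) at full weight versus 4.4% (3.8%) at 0.02; under ROI-level
  noise the down-weighting also *improves* agreement with the full-scan
  reference. Pass `completed_weight=1.0` to treat completed frames as
  measurements.

Completion never alters measured frames, and `mape` scores only the
hidden interval.

## Hybrid input functions

The population curve (PB-IDIF) is the average of dose-per-body-weight
normalised subject IDIFs resampled to the 66-frame midpoints (AUC
normalisation would be an easy variant; dose/weight matches the SUV
convention). For the DTW bridge,

    C_p(t) = C_image(t) outside (t₁, t₂),
             μ e^{−γ(t−t₁)} C_p0(t) inside,

with μ and γ fixed by continuity at the joins: μ = C_image(t₁)/C_p0(t₁)
and γ = ln[μC_p0(t₂)/C_image(t₂)]/(t₂−t₁). Joins are anchored at the
nearest *measured* sample times (last early and first late frame
midpoint), which makes the identity exact: a population curve equal to
the subject's own IDIF yields μ = 1, γ = 0 and a bridge identical to the
measured curve. For single-static-scan measures the population curve is
instead scaled by one factor α = AUC_image/AUC_PB-IDIF over the covered
part of the late window and stitched with the measured data.

## Simplified measures

* **SUV** uses the duration-weighted mean concentration in the 50–60 min
  window over dose/weight, with total injected activity in Bq and the
  1 g ≈ 1 mL density convention so SUV is dimensionless.
* **FUR** divides the same window mean by ∫₀ᵀ C_p with T = 55 min (the
  window centre; the window end is selectable).
* **Patlak** regresses C_PET(T)/C_p(T) on ∫₀ᵀC_p/C_p(T) over frames
  with midpoint ≥ t\* (default 30 min) by OLS; the slope estimates K_i.

Two properties of Patlak on 2T3k data are worth stating explicitly,
because they bound the attainable accuracy rather than indicate bugs:
with the vascular term in the measurement model, the asymptotic Patlak
slope is **(1−V_b)·K_i**, not K_i (a 4–8% deficit at typical V_b); and
the residual transient bias at t\* = 30 min decays monotonically as t\*
grows but is not zero — with the default bolus it is ≈ −0.9% for
cortex-like rates at V_b = 0. The test suite asserts both.

## Linearised voxel estimation

Double integration of the 2T3k system gives

    C_T = P₁C_p + P₂∫C_p + P₃∬C_p − θ₄∫C_T,    (irreversible: P₅ = 0)

with P₁ = V_b, P₂ = (1−V_b)K₁ + θV_b, P₃ = (1−V_b)K₁k₃, θ₄ = θ. The
∫C_T column is negated so all NNLS unknowns are nonnegative. Micro-
parameters are recovered by inverting the mapping (V_b = P₁,
K₁ = (P₂−P₁θ₄)/(1−P₁), k₃ = P₃/((1−P₁)K₁), k₂ = θ₄−k₃); degenerate
combinations (P₁ ≥ 1, K₁ ≤ 0, k₃ > θ₄) yield clipped or zeroed
parameters with a per-voxel flag, never NaNs. Plasma integrals are
exact; tissue integrals are cumulative trapezoids anchored at (0, 0).
On noise-free data the NNLS route agrees with the nonlinear fit to
better than 0.5% across the three tissue classes (2% asserted).
Patlak K_i maps use the same vectorised slope over frames ≥ 30 min.
Map noise is summarised as the coefficient of variation over an ROI
(population SD by default).

## Synthetic data

The arterial input is the classic tri-exponential FDG bolus model with
defaults A₁ = 851.1 kBq/mL/min, A₂ = 21.9, A₃ = 20.8 kBq/mL,
λ₁ = −4.134, λ₂ = −0.1191, λ₃ = −0.0104 min⁻¹ and 0.5 min delay.
Between-subject variability: the three amplitudes are scaled by the
subject's dose-per-weight (drawn as dose ~ N(230, 35) MBq, weight ~
N(62, 9) kg) and jittered by independent log-normal multipliers with
CV 15%, which makes the population curve a realistically imperfect
surrogate for any individual. Tissue parameters are drawn uniformly
from class priors: cortex K₁ 0.08–0.12, k₂ 0.10–0.16, k₃ 0.04–0.08,
V_b 0.03–0.06; muscle 0.02–0.04 / 0.15–0.30 / 0.01–0.03 / 0.01–0.04;
tumor 0.10–0.60 / 0.20–0.60 / 0.05–0.15 / 0.04–0.12.

Frame noise is Gaussian with σ_i = Sc·√(C(t_i)/Δt_i), independent per
frame, clipped at zero. Two scales are distinguished:
`DEFAULT_NOISE_SCALE = 0.6` is voxel/image-level noise (late-frame
relative SD ≈ 6% in cortex/tumor, ≈ 14% in cold muscle — the regime of
total-body reconstructions) and is used for phantom voxels;
`ROI_NOISE_SCALE = 0.075` models regional TACs, which average many
voxels (≈ 64-voxel ROI → image noise/8), and is used for cohort
ROI-quantification studies. This distinction is load-bearing: at
image-level noise the full-scan reference fit is itself so noisy that
*no* reduced-scan protocol can track it better than a late-window
surrogate, whereas at ROI level the DTW protocol cleanly outranks FUR
and SUV, as it does on patient ROI data.

What the generator does **not** emulate: correlated reconstruction
noise, partial-volume and spill-over effects on the IDIF, patient
motion, scanner breaks between the DTW windows, k₄ > 0 kinetics, and
tracer delay/dispersion differences between regions (subjects are
generated without delay; the delay-search operation is exercised on
explicitly shifted curves). Passing tests therefore demonstrate
correctness of the estimators under the stated statistical model, not
performance on patient data.

## Numerical choices and degenerate inputs

* Optimizer: scipy trust-region reflective with tight tolerances
  (xtol = ftol = gtol = 1e−10 for kinetic fits, 1e−12 for rational
  fits); multi-start grids as above.
* Frame membership rules (gap removal, Patlak qualification, static
  windows) use frame midpoints, making frames that straddle an edge
  unambiguous.
* The phantom and cohort generators are seed-deterministic via
  numpy Generator streams; identical seeds reproduce byte-identical
  fixtures and reports (report JSON excludes wall-clock timings from
  the determinism contract).
* Small negatives in measured TACs are preserved and flagged, not
  clipped; synthetic TACs are clipped at zero by construction.
* Problem sizes used by the shipped studies: 50 noise-free and
  25–100 noisy subjects for cohort checks, 16×16×4 or smaller phantoms
  for map checks. These run in minutes on one CPU and the estimator
  errors they measure are already dominated by model properties, not
  sample size.

## Known limitations

* The rational completion family cannot represent the bolus transit;
  its accuracy statement is confined to the bridged interval.
* Patlak's (1−V_b) attenuation and transient bias are inherent to the
  graphical method as printed and are reported, not corrected.
* The μ/γ bridge absorbs amplitude and mean decay-rate mismatch between
  subject and population curves but not curvature mismatch; with 15%
  amplitude jitter the residual gap-AUC error is a few percent, which
  bounds DTW K_i accuracy for outlier subjects at about the same level.
* FUR overestimates K_i by the intercept term int·C_p(T)/∫C_p; no
  correction is attempted, matching its use as a pure surrogate.
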