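# dtwpet

Kinetic quantification of dynamic total-body ¹⁸F-FDG PET with a
**dual-time-window (DTW) protocol**: instead of a continuous 60-minute
dynamic scan, the subject is scanned early (0–10 min) and late (ending at
60 min), the missing mid-scan tissue activity is completed by constrained
rational-function fitting, and the blood input function is bridged with a
rescaled population curve — after which full compartmental modeling
proceeds as if the whole scan existed.

The package is aimed at PET methodologists and physicists who want to
prototype or validate shortened dynamic protocols at desk scale: every
stage (input functions, tissue curves, 4-D phantoms) can be synthesized
with known ground truth, and the DTW estimates can be scored against
full-scan references and against the standard single-scan surrogates
(SUV, FUR, Patlak).

## The model

Tissue kinetics follow the irreversible two-tissue compartment model
(2T3k), with plasma concentration C_p, free tracer C₁ and phosphorylated
tracer C₂:

    dC₁/dt = K₁ C_p(t) − (k₂ + k₃) C₁(t)
    dC₂/dt = k₃ C₁(t)                         (k₄ = 0)
    C_PET(t) = V_b C_p(t) + (1 − V_b)(C₁ + C₂)

The net influx rate **K_i = K₁k₃/(k₂+k₃)** (mL/g/min) is the clinically
relevant macro-parameter. Five estimation routes are implemented:

| route | data needed | estimator |
|---|---|---|
| full 2T3k | 60-min dynamic + IF | bounded weighted NLLS (`fit_2t3k`) |
| DTW 2T3k | 10 min + late window | rational completion + hybrid IF + NLLS (`run_dtw_pipeline`) |
| Patlak | frames ≥ t\* + IF | OLS slope of the graphical linearisation (`patlak`) |
| FUR | one late frame + IF | C_PET(T) / ∫₀ᵀC_p (`fur`) |
| SUV | one late frame | C_PET(T)/(dose/weight) (`suv`) |

Voxel-wise maps use the linearised 2T3k form solved per voxel with
Lawson–Hanson NNLS (`fit_parametric_images`), with the micro-parameters
recovered from the linear coefficients in closed form.

## Worked example

`examples/02_dtw_completion.py` truncates a noise-free cortex-like TAC on
the standard 66-frame schedule to three DTW configurations and scores the
rational completion over the hidden frames:

```
windows  10+20 min: 50 of 66 frames kept, gap MAPE = 0.58%
windows  10+10 min: 45 of 66 frames kept, gap MAPE = 1.24%
windows   10+5 min: 43 of 66 frames kept, gap MAPE = 1.55%
```

MAPE is the mean absolute percentage error of the estimated mid-scan
frames against the hidden truth; shorter late windows leave the
interpolation less anchored, so the error grows as the protocol shrinks.
`examples/05_method_comparison.py` runs a 12-subject noisy cohort and
prints per-region R² of each surrogate against the full-scan reference
K_i:

```
region      DTW 10+5       FUR    Patlak       SUV
cortex         0.973     0.895     0.967     0.705
muscle         0.929     0.901     0.984     0.855
tumor          0.999     0.992     0.995     0.946
```

The DTW protocol tracks the reference best; SUV is weakest because
dose-per-weight normalisation cannot remove between-subject delivery
variability. The other examples cover the forward model round-trip, the
hybrid input-function bridge (μ, γ, AUC error), and NNLS vs Patlak
parametric phantom maps.

A thin CLI mirrors the library: `dtwpet synth`, `dtwpet quantify`,
`dtwpet dtw-simulate`, `dtwpet parametric-image`, `dtwpet compare`
(see `--help` on each verb).

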