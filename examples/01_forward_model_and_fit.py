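"""Simulate a tissue curve with the irreversible two-tissue model and
recover its parameters by weighted nonlinear fitting.

The forward model is exact (analytic convolution against a
piecewise-linear input function), so on noise-free data the fit should
return the generating parameters almost to machine precision.
"""

import numpy as np

from dtwpet import (
    KineticParams,
    build_frame_schedule,
    feng_input,
    fit_2t3k,
    model_tac,
)

schedule = build_frame_schedule()  # 24x5s, 6x10s, 6x30s, 6x60s, 24x120s
input_fn = feng_input()  # tri-exponential FDG bolus
truth = KineticParams(K1=0.10, k2=0.13, k3=0.06, Vb=0.045)

tac = model_tac(input_fn, truth, schedule)  # frame-averaged tissue TAC
fit = fit_2t3k(tac, input_fn)

print(f"{len(schedule)} frames spanning {schedule.span[1]:.0f} min")
print(f"{'':10s}{'truth':>10s}{'fitted':>10s}")
for name in ("K1", "k2", "k3", "Vb"):
    print(f"{name:10s}{getattr(truth, name):10.4f}"
          f"{getattr(fit.params, name):10.4f}")
print(f"{'Ki':10s}{truth.Ki:10.4f}{fit.params.Ki:10.4f}")
print(f"weighted RSS = {fit.weighted_rss:.3e}")
print()
print("Ki = K1*k3/(k2+k3) is the net FDG influx rate (mL/g/min); the")
print("round-trip confirms the fit recovers all four micro-parameters")
print("from noise-free frame data.")
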