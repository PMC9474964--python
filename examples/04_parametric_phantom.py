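"""Voxel-wise parametric imaging of a small 4-D phantom.

A 16x16x4 phantom with blood-pool, cortex-, muscle- and tumor-like
regions is fitted voxel-by-voxel with the linearised (NNLS) model, and
a Patlak Ki map is generated for comparison.  The coefficient of
variation (CoV) inside the muscle region quantifies map noise.
"""

import numpy as np

from dtwpet import NoiseModel, feng_input, fit_parametric_images, roi_cov
from dtwpet.synthetic import simulate_phantom

input_fn = feng_input()
image, masks, truth = simulate_phantom(
    rng=1, dims=(16, 16, 4), noise=NoiseModel(0.6)  # voxel-level noise
)

maps_nnls = fit_parametric_images(image, input_fn, method="nnls_2t3k")
maps_patlak = fit_parametric_images(image, input_fn, method="patlak")

print("region medians (NNLS) vs generating truth:")
for name, params in truth.items():
    if params is None:
        continue
    med_ki = float(np.median(maps_nnls.Ki[masks[name]]))
    med_k1 = float(np.median(maps_nnls.K1[masks[name]]))
    print(f"  {name:7s} Ki {med_ki:.4f} (truth {params.Ki:.4f}),"
          f" K1 {med_k1:.4f} (truth {params.K1:.4f})")

cov_nnls = roi_cov(maps_nnls.Ki, masks["muscle"])
cov_patlak = roi_cov(maps_patlak.Ki, masks["muscle"])
print(f"\nmuscle Ki-map CoV: NNLS {cov_nnls:.2f}, Patlak (30-60 min) "
      f"{cov_patlak:.2f}")
print()
print("NNLS uses all 66 frames and is markedly less noisy than Patlak,")
print("which regresses only the frames beyond t* = 30 min — the same")
print("noise ordering seen in whole-body Ki images.")
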