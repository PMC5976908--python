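"""Recover model parameters from a noisy synthetic growth curve.

Generates a sparse 12-point dataset (sigma = 0.1 PD measurement noise) from
the experiment-A normoxia parameters, fits all five parameters by multistart
constrained least squares, and prints the recovered values next to the
generating ones.  The senescence midpoint T is typically recovered to well
within a day.
"""

import numpy as np

from mscgrowth import PARAMETER_NAMES, SyntheticDesign, fit_full, generate_growth_curve
from mscgrowth.presets import EXPERIMENT_A

true = EXPERIMENT_A["normoxia"]
design = SyntheticDesign(
    sampling_times=np.linspace(10.0, 120.0, 12), noise_sd=0.1, seed=7
)
data = generate_growth_curve(true, design)

result = fit_full(data)

print(f"fit converged: {result.converged}  (cost J = {result.cost:.4g}, "
      f"{result.n_starts} starts)")
print(f"{'parameter':>10} {'true':>9} {'fitted':>9}")
for name in PARAMETER_NAMES:
    print(f"{name:>10} {getattr(true, name):9.4f} {getattr(result.params, name):9.4f}")
print("\nResiduals are on the PD scale; with sigma = 0.1 PD noise the cost"
      "\napproximates n * sigma^2 ~ 0.12 at the true parameters.")
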