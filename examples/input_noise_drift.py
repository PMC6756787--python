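"""Drift coordination under independent velocity-input noise.

Three modules receive the same smooth trajectory plus independent white
velocity noise (eta = 0.02 m s^-1/2).  Coupled, their scaled phase paths
stay nearly identical (tiny pairwise mean-square displacement) and the
position-MSE accumulates about three times slower than uncoupled -- the
noise is averaged over the modules by the coupling.
"""

import numpy as np

from gridlock.experiments import ExperimentConfig, drift_coordination

cfg = ExperimentConfig(
    scenario="drift_coordination", backend="reduction", seed=1, trials=60, T=20.0, dt=1e-4, N=200
)
out = drift_coordination(cfg)

msd_c = max(float(v[-1]) for v in out["coupled"].msd_pairs.values())
msd_u = max(float(v[-1]) for v in out["uncoupled"].msd_pairs.values())
print(f"worst pairwise MSD between scaled module paths at T=20 s:")
print(f"  coupled   {msd_c:.2e} m^2")
print(f"  uncoupled {msd_u:.2e} m^2   ({msd_u / msd_c:.0f}x larger)")
print(f"MSE slope ratio uncoupled/coupled = {out['mse_slope_ratio']:.2f} "
      f"(noise averaging over m=3 modules predicts ~3)")
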