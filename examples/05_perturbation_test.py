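"""Test attractor stability with off-manifold perturbations.

Kicks the latent state orthogonally to the slow dimension during three
windows (the male pauses during and after each, as in a remote
interruption of mating), fits the model on unperturbed data only, and asks
whether the frozen model predicts the held-out relaxation back to the
attractor line.
"""

import numpy as np

from linedyn import SimConfig
from linedyn.rslds import FitConfig, fit_excluding_windows
from linedyn.synthetic import (
    simulate_emissions,
    simulate_latents,
    simulate_male_bouts,
    simulate_perturbation,
    suppress_bouts,
)

cfg = SimConfig(seed=0)
windows = [(1500, 1530), (3000, 3030), (4500, 4530)]
kick = np.array([0.0, 0.0, 0.35])  # orthogonal to the slow dimension

male = suppress_bouts(simulate_male_bouts(cfg), windows, margin_frames=250)
lat0 = simulate_latents(cfg, male)
latp = simulate_perturbation(lat0, cfg, male, windows, kick)
raster = simulate_emissions(latp, cfg)

res = fit_excluding_windows(raster, windows, K=1, D=3,
                            config=FitConfig(n_iters=30))
print(f"held-out post-kick prediction cvR2: {res['cv_r2']:.2f} "
      "(the model never saw the perturbed frames)")

diff = latp.x - lat0.x  # paired difference = pure kick response
a_fast = np.exp(-1.0 / (cfg.tau_fast * cfg.frame_rate))
band = cfg.innovation_sd[2] / np.sqrt(1 - a_fast**2)
horizon = int(3 * cfg.tau_fast * cfg.frame_rate)
for _, b in windows:
    print(f"  window ending at frame {b}: displacement "
          f"{abs(diff[2, b - 1]) / band:.1f} -> "
          f"{abs(diff[2, b + horizon]) / band:.1f} noise-band s.d. "
          "within 3 tau_fast (back on the attractor)")
print(f"slow dimension displaced by at most "
      f"{np.abs(diff[0]).max():.2e} (orthogonal kick leaves it untouched)")
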