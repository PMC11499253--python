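"""Method-independent validation with a FORCE-trained RNN.

Trains a tanh rate network (g = 1.5, tau = 0.5 s) by recursive least
squares so its recurrent readout reproduces the session traces, then
reverse-engineers it: minimizing the state speed finds the network's
fixed/slow points.  A line attractor appears as a collinear band of slow
points — confirming the rSLDS geometry without a state-space model.
"""

import numpy as np

from linedyn import SimConfig, simulate_session
from linedyn.force_rnn import (
    ForceConfig,
    ForceRNN,
    find_fixed_points,
    train_force,
)
from linedyn.integrator import behavior_indicators

session = simulate_session(SimConfig(seed=0, duration_frames=2000))
u = behavior_indicators(session.male_bouts, 2000)
rnn = train_force(session.raster.data, 10.0, inputs=u,
                  config=ForceConfig(n_passes=4, seed=0))
print(f"median per-unit reconstruction r2: {np.median(rnn.r2):.2f} "
      f"(training error {rnn.train_error[0]:.2f} -> "
      f"{rnn.train_error[-1]:.2f} across passes)")

# a planted line-attractor network: slow points line up
N = 200
direction = np.ones(N) / np.sqrt(N)
planted = ForceRNN(J=np.outer(direction, direction) / 1.5,
                   W_in=np.zeros((N, 1)), config=ForceConfig(g=1.5))
rng = np.random.default_rng(1)
inits = np.vstack([s * direction + 0.02 * rng.standard_normal(N)
                   for s in np.linspace(-0.6, 0.6, 13)])
fps = find_fixed_points(planted, n_inits=13, tol=1e-6, slow_tol=1e-3,
                        inits=inits, seed=0)
centred = fps.points - fps.points.mean(axis=0)
sv = np.linalg.svd(centred, compute_uv=False)
print(f"{len(fps.points)} slow points found; PCA line fit R2 = "
      f"{sv[0]**2 / (sv**2).sum():.3f} "
      "(collinear slow points = a line attractor)")
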