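"""Generate a synthetic mating-assay imaging session and inspect it.

Builds a 10-minute receptive-day session: male sniff/mount/intromission
bouts with log-normal durations and ~13.7-s copulation IBIs, a latent
system with one slow integrating dimension (tau = 100 s), linear-Gaussian
calcium emissions for 100 neurons, and female annotations whose acceptance
depends on the slow latent.
"""

import numpy as np

from linedyn import SimConfig, simulate_session
from linedyn.behavior import bout_ibi_stats

session = simulate_session(SimConfig(seed=0))

stats = bout_ibi_stats(session.male_bouts)
print(f"male copulation bouts : {len(stats['durations_s'])}")
print(f"mean bout duration    : {stats['mean_duration_s']:.1f} s")
print(f"mean IBI              : {stats['mean_ibi_s']:.1f} s "
      "(the inter-bout interval the integrator must bridge)")

taus = session.config.latent_taus_seconds()
print(f"ground-truth taus     : {np.round(taus, 1)} s "
      "(one slow integrating dimension, two fast)")
print(f"raster                : {session.raster.n_neurons} neurons x "
      f"{session.raster.n_frames} frames at "
      f"{session.raster.frame_rate:g} Hz, z-scored")

accept = session.female_bouts.select(group="accept")
resist = session.female_bouts.select(group="resistance")
print(f"female accept bouts   : {len(accept)}, resistance: {len(resist)} "
      "(acceptance becomes likelier as the slow latent ramps)")
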