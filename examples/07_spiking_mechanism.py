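"""Mechanistic spiking model of the integrator.

1,000 LIF neurons with feedback inhibition; a 200-neuron subnetwork has
dense recurrent connectivity and 20-s synapses.  Twenty input pulses make
the subnetwork's synaptic activation ramp (it integrates), while the rest
of the network resets between pulses.  Hypothesis 1 (no slow synapses)
abolishes the ramp; hypothesis 2 reweights the external input instead.
"""

import numpy as np

from linedyn.spiking import (
    SpikingConfig,
    apply_hypothesis,
    pulse_stimulus,
    simulate,
    subnetwork_summary,
)

cfg = SpikingConfig(seed=0)
stim = pulse_stimulus(cfg)

for label, config in [("default", cfg),
                      ("h1 (tau_s 20 s -> 100 ms)",
                       apply_hypothesis(cfg, "h1")),
                      ("h2 (input reweighted)",
                       apply_hypothesis(cfg, "h2"))]:
    state = simulate(config, stim)
    summ = subnetwork_summary(state, stim["onsets"], stim["isi"],
                              stim["width"])
    print(f"{label:28s} subnetwork ramp rho = "
          f"{summ['ramp_rho_sub']:+.2f}   control decay fraction = "
          f"{summ['rest_decay_fraction']:.3f}")
print("rho ~ 1 means the persisting activation grows monotonically over "
      "the 20 pulses; only the slow-synapse subnetwork integrates.")
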