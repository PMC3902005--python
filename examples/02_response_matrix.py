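"""From simulated spike trains to the normalized stimulus-response matrix.

Simulates one day-30 stimulation session (50 pulses to each of the 59
electrodes, every 300 ms) plus a 60 s spontaneous session from the same
latent network, counts evoked spikes in a 100 ms window after each pulse,
and subtracts the per-electrode spontaneous baseline.
"""

import numpy as np

import meanet as m
from meanet.synth import session_seed

emap = m.standard_mea_layout()
schedule = m.GrowthSchedule()
net = m.generate_latent_trajectory(emap, schedule, seed=7)[29]  # day 30

stim = m.simulate_stimulation_session(emap, net, seed=session_seed(7, 0, 30, "stimulation"))
spont = m.simulate_spontaneous(emap, 30, m.FiringParams(), 60.0,
                               seed=session_seed(7, 0, 30, "spontaneous"))

window = m.WindowSpec(window_ms=100.0)
counts = m.count_evoked(stim, window, emap)
baseline = m.spontaneous_baseline(spont, window, emap)
rm = m.build_z(counts, baseline, emap, window)

print(f"latent network edges     : {net.n_edges}")
print(f"stimulation pulses       : {len(stim.pulses)} (59 electrodes x 50 trials)")
print(f"spikes in stim session   : {len(stim.spikes)}")
print(f"mean spontaneous baseline: {baseline.mean():.3f} spikes/window")
print(f"Z matrix                 : {rm.z.shape}, range [{rm.z.min():.2f}, {rm.z.max():.2f}]")
print()
print("Entries near zero are unconnected pairs (evoked counts match the")
print("spontaneous rate); strongly positive entries mark electrodes that")
print("reliably fire extra spikes after stimulation of a particular site.")
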