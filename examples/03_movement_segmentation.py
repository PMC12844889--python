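"""Segment behavior into rest and movement, and detect movement onsets.

Velocity is computed from the tracked centroid, cleaned with a 1 s median
filter, and classified with the 0.5 cm/s threshold; onsets additionally
require > 0.5 cm/s sustained for 2 s after 4 s of rest, with an in-place
dither filter (1 cm displacement within 1 s).  Bout statistics of this kind
are what drug/genotype comparisons operate on.
"""

import numpy as np

from spncoact import behavior, session_io, synthetic

sim = synthetic.simulate_session(synthetic.SimConfig(n_cells=5, duration=600.0, seed=3))
grid = session_io.align_streams(sim.session, sim.tracking)
raw_v = behavior.compute_velocity(sim.tracking)
loco = behavior.filter_velocity(raw_v, sim.tracking, grid)
epochs = behavior.classify_epochs(loco)
onsets = behavior.detect_onsets(sim.tracking)

print(f"mean velocity: {np.nanmean(loco.velocity):.2f} cm/s")
print(f"fraction of time at rest: {epochs.fraction_rest:.2f}")
print(f"bouts: {epochs.n_bouts}, mean bout length {epochs.mean_bout_length:.1f} s")
print(f"movement onsets passing all rules: {len(onsets)}")
print(f"first onsets (s): {np.round(onsets[:5], 1)}")
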