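"""Generate a ground-truth-annotated synthetic miniscope session.

Builds a 10-minute session of 40 striatal cells with two spatial ensembles,
writes the delimited-text files a real pipeline run would consume (traces,
timestamps, centroids, tracking) plus the ground truth, and prints what was
made.  The printed rates are events per second per cell; rest/move fractions
come from the simulated bout structure.
"""

import numpy as np

from spncoact import synthetic

cfg = synthetic.SimConfig(n_cells=40, duration=600.0, n_ensembles=2, seed=1)
sim = synthetic.simulate_session(cfg)
outdir = synthetic.write_session(sim, "scratch/example_session")

gt = sim.ground_truth
n_events = sum(len(t) for t in gt.event_times)
print(f"wrote session to {outdir}")
print(f"cells: {cfg.n_cells}, frames: {sim.session.n_frames} at {cfg.acq_rate:g} fps")
print(f"ensemble members: {(gt.ensemble_membership >= 0).sum()} of {cfg.n_cells}")
print(f"ground-truth events: {n_events} "
      f"({n_events / cfg.n_cells / cfg.duration:.4f} events/s per cell)")
print(f"fraction of time moving: {gt.state_sequence.mean():.2f}")
print(f"mean velocity while moving: {np.mean(gt.true_velocity[gt.state_sequence]):.2f} cm/s")
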