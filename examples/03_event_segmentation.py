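"""Segment a group-average run into 16 events with the constrained HMM.

The model walks through events 1..16 in order (stay or advance only,
start and end pinned) and returns an event x timepoint probability
matrix; boundaries are where the most probable event increments.
"""

import numpy as np

from emodyn import HmmConfig, SimSpec, entropy_trace, find_boundaries, fit, simulate_cohort
from emodyn.power import match_fraction
from emodyn.timeline import all_builtin_timelines

tls = {k: v for k, v in all_builtin_timelines().items() if k[0] == "A"}
spec = SimSpec(n_subjects=20, n_units=80, n_features=40, snr=0.5,
               shared_voxel_map=True, seed=1)
ds = simulate_cohort(spec, tls)
group = ds.group_mean("A", 1)

seg = fit(group, HmmConfig(n_events=16))
rec = find_boundaries(seg)
true = ds.boundaries[("A", 1)]

print(f"group average of 10 subjects, {seg.T} TRs, K = {seg.K} events")
print(f"log-likelihood: {seg.log_likelihood:.1f} after {len(seg.ll_trace)} EM steps")
print(f"\nrecovered boundaries: {rec.tolist()}")
print(f"true switch TRs     : {true.tolist()}")
rate = match_fraction(true, rec, tol_tr=1)
print(f"\n{rate:.0%} of true boundaries recovered within +/-1 TR (1.5 s)")

h = entropy_trace(seg)
print(f"posterior entropy: mean {h.mean():.2e}, at boundaries {h[rec].mean():.2e} nats")
print("entropy peaks exactly where the model is uncertain between adjacent")
print("events — the data-driven signature of a transition.")
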