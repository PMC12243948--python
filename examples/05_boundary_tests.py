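"""Do neural patterns track the composer-defined transitions?

Two complementary tests on a group-average run: (1) timepoint pattern
correlations should be higher within events than across adjacent events;
(2) HMM posterior entropy should peak at the composer-defined switch
TRs.  Both use length-preserving shuffles of the event structure as the
null.
"""

import numpy as np

from emodyn import HmmConfig, SimSpec, fit, music_tr_labels, simulate_cohort
from emodyn.boundaries import boundary_pattern_test, entropy_match_test
from emodyn.timeline import all_builtin_timelines

tls = {k: v for k, v in all_builtin_timelines().items() if k[0] == "A"}
spec = SimSpec(n_subjects=20, n_units=80, n_features=40, snr=0.5,
               shared_voxel_map=True, seed=1)
ds = simulate_cohort(spec, tls)
group = ds.group_mean("A", 1)
labels = music_tr_labels(tls[("A", 1)])

bp = boundary_pattern_test(group, labels, n_perm=1000, seed=0)
print("hypothesis-driven (within - across event correlation):")
print(f"  observed {bp.observed:.3f}, null {bp.null_values.mean():.3f}, "
      f"z = {bp.z:.2f}, p = {bp.p:.4f}")

seg = fit(group, HmmConfig(n_events=16))
em = entropy_match_test(seg, ds.boundaries[("A", 1)], n_perm=1000, seed=0,
                        window_tr=1)
print("\ndata-driven (posterior entropy at transitions):")
print(f"  observed {em.observed:.2e}, null {em.null_values.mean():.2e}, "
      f"z = {em.z:.2f}, p = {em.p:.4f}")
print("\nboth p-values are small: the region's patterns are stable within")
print("events and reorganize at the emotional transitions.")
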