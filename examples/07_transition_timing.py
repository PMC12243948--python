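"""Does the neural transition come later when the valence changes?

For every event preceded by a same-valence exemplar in one version and a
different-valence exemplar in the other, a 2-state HMM is fit to the
(predecessor + event) window of each version; summing the expected event
index counts TRs already assigned to the new event, so a higher sum
means an earlier transition.
"""

from emodyn import SimSpec, simulate_cohort
from emodyn.timeline import all_builtin_timelines
from emodyn.timing import valence_timing_contrast

tls = all_builtin_timelines()
spec = SimSpec(n_subjects=20, n_units=30, n_features=15, snr=1.0,
               timing_delay_tr=4, context_shift=0.0,
               shared_voxel_map=True, seed=3)
ds = simulate_cohort(spec, tls)
gf = {(p, v): ds.group_mean(p, v) for p in ("A", "B") for v in (1, 2)}

out = valence_timing_contrast(gf, tls, n_perm=1000, seed=0)
tab = out["events"]
print(tab[["piece", "emotion", "exemplar_no", "diff_tr", "diff_s"]].to_string(index=False))
print(f"\nmean shift: {out['shift_tr']:.2f} TRs = {out['shift_seconds']:.2f} s")
print(f"one-sample t = {out['result'].observed:.2f}, p = {out['result'].p:.4f}")
print("\nthe generator delayed valence-crossing transitions by 4 TRs (6 s);")
print("the paired contrast recovers that shift from the fitted HMMs alone.")
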