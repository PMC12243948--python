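"""Behavioral validation: button presses and retrospective ratings.

Simulated raters toggle emotion labels while listening; the tests ask
whether presses cluster at transitions, whether intended emotions were
felt, how long the feeling takes to arrive as a function of context, and
whether retrospective ratings are version-dependent.
"""

import numpy as np

from emodyn import simulate_button_presses, simulate_ratings
from emodyn.behavior import (
    intended_emotion_test,
    press_transition_test,
    rating_context_correlation,
    time_to_threshold_contrast,
)
from emodyn.timeline import all_builtin_timelines

tls = all_builtin_timelines()
presses = {k: simulate_button_presses(tl, seed=11) for k, tl in tls.items()}
tl = tls[("A", 1)]

pt = press_transition_test(presses[("A", 1)],
                           np.array([e.onset_s for e in tl.events[1:]]),
                           tl.total_music_s, n_perm=1000, seed=0)
print(f"presses at transitions: z = {pt.z:.2f}, p = {pt.p:.4f}")

ie = intended_emotion_test(presses[("A", 1)], tl, n_perm=1000, seed=0)
print("\nraters (of 36) selecting the intended emotion during its events:")
for emo, r in ie.items():
    print(f"  {emo:<10} mean = {r.observed:5.2f}  p = {r.p:.3f}")

ttc = time_to_threshold_contrast(presses, tls, n_perm=1000, seed=0)
print(f"\nlatency to report positive emotions, different- minus same-valence")
print(f"predecessor: {ttc['positive'].observed:.2f} s (p = {ttc['positive'].p:.4f})")
print("(the generator penalizes valence-crossing onsets by 9 s)")

ratings = simulate_ratings(tls, n_subjects=20, context_effect=0.5, seed=1)
rcc = rating_context_correlation(ratings, n_perm=1000, seed=0)
print(f"\nrating similarity, within- minus across-version pairs: "
      f"{rcc.observed:.3f} (p = {rcc.p:.4f})")
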