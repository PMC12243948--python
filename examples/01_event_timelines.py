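"""The composer-defined event structure of the two pieces.

Loads the bundled event tables, types every transition by valence, and
projects one version onto the fMRI sampling grid (TR = 1.5 s).
"""

from emodyn import (
    all_builtin_timelines,
    builtin_timeline,
    catalogue_events,
    to_tr_grid,
    transition_counts,
)

tls = all_builtin_timelines()
cat = catalogue_events(tls)
print(f"unique musical events across both pieces: {len(cat)}")
print(f"nostalgic bookends: {sum(1 for k in cat if k[0] == 'nostalgic')}")

tl = builtin_timeline("A", 1)
print(f"\nPiece A, Version 1 ({len(tl.events)} events):")
for e in tl.events[:4]:
    print(f"  {e.index:2d}. {e.emotion.value:<10} {e.onset_s:5.0f}-{e.offset_s:5.0f} s"
          f" ({e.duration_s:.0f} s)")
print("  ...")

counts = transition_counts(tl)
print(f"\ntransitions: {counts['same_valence']} same-valence, "
      f"{counts['different_valence']} different-valence, "
      f"{counts['excluded']} excluded (nostalgic endpoint)")

grid = to_tr_grid(tl)
print(f"\nfull scanning run: {len(grid)} images "
      f"(4 TRs silence + 597 TRs music + 6 TRs silence)")
print("a value of -1 marks silence or an interlude; otherwise the 0-based")
print("index of the event sounding at that TR.")
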