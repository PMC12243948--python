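# emodyn

Event segmentation, functional alignment, and context analyses for
dynamic-emotion music fMRI designs — with a synthetic-data generator
that makes the whole pipeline testable end-to-end.

## The problem

How does the brain track *transitions* between emotional states, and
how does the recent emotional context reshape the response to the same
stimulus?  One way to ask this with fMRI: commission music composed as a
sequence of discrete emotional events (calm, happy, sad, anxious, with
dreamy/nostalgic bookends), create two versions of each piece that
reorder the events so the same music is heard after a different
predecessor, and test whether neural patterns (i) segment at the
composed transitions, (ii) differ by version (context), and (iii)
transition later when the valence changes.

`emodyn` is a library for exactly this family of analyses, aimed at
researchers who want to run, extend, or sanity-check such a design.  It
provides:

* **stimulus timelines** — the four event tables (2 pieces × 2
  versions, 16 events each, onsets/offsets in seconds) bundled as data,
  with transition typing by valence and projection onto the TR grid;
* **a synthetic cohort generator** — stable per-event spatial patterns,
  context-keyed perturbations, valence-dependent transition delays,
  AR(1) + drift + white noise, counterbalanced version assignment,
  button-press and rating behavior, all with ground truth attached;
* **a constrained event-segmentation HMM** — forward-only states with
  stay probability (K−1)/T, pinned start/end, isotropic Gaussian
  emissions on z-scored patterns; fit by deterministic multi-start EM.
  For data `X ∈ R^{T×F}` it returns the event×timepoint posterior
  `γ` (columns sum to 1), from which boundaries (argmax increments),
  the entropy trace `H_t = −Σ_k γ_{kt} ln γ_{kt}` and the expected
  event index `E_t = Σ_k k·γ_{kt}` are derived;
* **a deterministic shared response model (SRM)** — per-subject
  orthonormal transforms `W_i` and a shared course `S` minimizing
  `Σ_i ‖X_i − S W_iᵀ‖²`, fit on a held-out alignment run and applied to
  the music runs;
* **permutation statistics** — within- vs across-event timepoint
  correlations, entropy at transitions, split-half context similarity,
  paired 2-state HMM timing contrasts, behavioral press/rating tests —
  each against a design-preserving shuffle null;
* **searchlight + cluster-extent correction** on a vertex graph, and a
  **power harness** for design-phase sample-size planning.

## Worked example

Segment a simulated group-average run (20 subjects, snr 0.5) into its
16 events and test boundary tracking:

```bash
python examples/03_event_segmentation.py
python examples/05_boundary_tests.py
```

```
group average of 10 subjects, 597 TRs, K = 16 events
log-likelihood: -41354.0 after 3 EM steps

recovered boundaries: [47, 89, 133, 167, 209, 247, 283, 325, 355, 381, 423, 457, 492, 517, 557]
true switch TRs     : [46, 88, 132, 166, 208, 246, 282, 324, 354, 380, 422, 456, 491, 516, 556]

100% of true boundaries recovered within +/-1 TR (1.5 s)
```

Every recovered boundary sits one TR after the true switch — the causal
(hemodynamic-style) smoothing delays the detectable pattern change by
one sample, which is why recovery is scored at ±1 TR.  The permutation
tests on the same data:

```
hypothesis-driven (within - across event correlation):
  observed 0.621, null 0.387, z = 4.21, p = 0.0010

data-driven (posterior entropy at transitions):
  observed 3.76e-15, null 2.79e-16, z = 5.02, p = 0.0010
```

Timepoint patterns correlate 0.62 within events versus 0.39 across
adjacent events under the length-preserving shuffle null, and the HMM's
uncertainty concentrates at the composed transitions — both signatures
of neural event segmentation.  `examples/06_context_patterns.py` and
`examples/07_transition_timing.py` show the context analyses the design
exists for: the same event evokes version-dependent patterns
(z ≈ 10 at context_shift 0.5), and the fitted transition shift recovers
the planted 6 s delay for valence-crossing transitions.

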