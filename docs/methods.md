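# Methods

## Model

The core of the package is a gradient-frequency network: 145 mutually
uncoupled Hopf oscillators, each driven by the same scalar stimulus and
distinguished only by intrinsic frequency. Frequencies follow
`f_i = f_min (f_max/f_min)^((i−1)/(n−1))` with defaults 0.25–4 Hz, which
places oscillator 73 at exactly 1 Hz and makes the bank geometrically
symmetric about it (`f_i · f_{n+1−i} = 1`). Each oscillator obeys the fully
expanded, stimulus-driven Hopf normal form

    dz/dt = z (α + iω + β ε |z|⁴ / (1 − ε |z|²))
            + x/(1 − √ε x) · 1/(1 − √ε z̄),

α = −0.1 (s⁻¹, damping: the origin is the unforced attractor),
β = −0.1 (amplitude compression), ε = 0.5 (scale factor), ω = 2π f_i.
The coupling denominators use the √ε / conjugate convention of the
canonical derivation of this oscillator family; both factors are convergent
power series only while √ε·|x| < 1 and √ε·|z| < 1, which the code enforces
as a hard domain (configuration error for stimuli, integration abort with
the offending oscillator and time for states). A config switch
(`coupling.radical: plain`) exposes the variant with ε in place of √ε and
no conjugation for sensitivity analysis.

## Stimuli

A rhythm is three inter-onset intervals summing to one bar (1 s). The study
grid enumerates all IOI triples on the 1/19-s lattice with each IOI at
least 3/19 s — the count is the composition number C(12, 2) = 66. A trial
is 8 bars with the rhythm in bars 3, 5, 7 (its fourth onset falling on the
following downbeat). Metric priming adds isochronous beats — duple {0, ½},
triple {0, ⅓, ⅔} within the bar — in the non-rhythm bars 1, 2, 4, 6, 8, so
that the induced meter persists through the rhythm presentations;
coincident onsets merge into one event. The priming-bar set is
configurable (`trial.priming_bars`), e.g. `(1, 2)` restricts priming to the
two lead-in bars. Onset trains are encoded as rectangular pulses, 20 ms
wide, amplitude 0.25, at 1 kHz. These encoding values are modelling
choices, not empirical constraints: 1 ms resolves the 1/19-s lattice to
within 0.6% of an IOI, 20 ms is a typical percussive-attack scale, and
amplitude 0.25 keeps √ε·x ≈ 0.18, safely inside the coupling domain.

## Numerics

Integration is fixed-step classical RK4 at the stimulus sample rate with
zero-order hold of the stimulus within a step, initial state z = 0 (the
unforced attractor), no randomness anywhere on the model path. Convergence
was verified by step halving: at 2 kHz every activation entry changes by
under 0.03% (per-step normalized) and 1 of the 66 no-meter category
assignments flips. Map-level runs batch all trials of a condition into one
vectorized integration that accumulates the window sums on the fly —
arithmetic-identical to per-trial integration followed by summation.

## Readout

Activation patterns sum |z| over the second half of the trial, inclusive
at both window ends (4001 steps of an 8-s, 1-kHz trial). Patterns are
never normalized; Euclidean nearest-prototype classification is therefore
deliberately scale-sensitive (tested). The dynamic readout applies the
same half-window rule to the truncated trial ([t/2, t] at each t;
`dynamic.window: fixed_start` instead pins the window start), yielding
category-over-time traces. SNR is peak activation over the sum of the
rest, +∞ for a perfectly concentrated pattern, and explicitly *undefined*
(an error, not NaN) for an all-zero pattern.

The 12 prototype categories ship as a data file
(`rhythmcat/data/prototypes.csv`), because the identity of the most common
human transcription categories is an empirical input: the complete
integer-ratio families with sums 3–5 (1-1-1; 1-1-2, 1-2-1, 2-1-1; 1-2-2,
2-1-2, 2-2-1, 1-1-3, 1-3-1, 3-1-1) plus 1-2-3 and 3-2-1. All twelve fit
the grid's 3/19-s IOI floor. The five entries beyond the commonly cited
seven are flagged `verified=no`; all pipelines are agnostic to the list's
content and accept a replacement CSV.

## Statistics

Agreement between two category maps is the raw count of same-label rhythms
after dropping exclusions. The permutation test reassigns one side's
labels uniformly at random (default 10,000 times, seeded PCG64) and uses
the add-one convention p = (1 + #{score ≥ observed})/(1 + n), so p is
never exactly zero; two-tailed p doubles the smaller tail (capped at 1),
with an extreme-count-from-the-mean variant available. Because the
agreement score is an integer with few typical values, the null
distribution of p is discrete: p is valid (coverage at or below nominal)
and mildly conservative rather than exactly uniform — measured coverage at
α = 0.05 is ≈ 0.035 over 200 null replicates. Relative entropy of a choice
distribution is Shannon entropy over log k, with k the number of
*available* categories (12), not the number observed. Pearson correlation
between model SNR and externally supplied behavioral consistency maps is
included for replication against digitized human data; no such data ship
with the package.

## Category-map geometry

`convexity_report` measures, per category, the fraction of same-label grid
pairs whose straight segment (sampled in the barycentric embedding of the
IOI simplex and snapped to nearest grid points) stays inside the label's
region — a soft diagnostic of region convexity, 1.0 for filled convex
regions and below 1.0 for disconnected islands.

## Expected agreement levels, and a known limitation

With all defaults, the model-only cross-condition agreements are
duple-vs-none 24.2% and triple-vs-none 15.2% — duple above triple by
9.1 points, the modal no-meter category 1-1-1, and broadly convex category
regions. The *ordering* and the size of the duple−triple difference
reproduce previously reported behavior of this model class; the *absolute*
agreement levels do not (values near 77%/71% have been reported). The
discrepancy has a clear mechanism: at pulse amplitude 0.25 the bank
operates in a near-linear regime (max |z| ≈ 0.06), so priming adds a
nearly rhythm-independent offset to every activation pattern whose norm
(~150) far exceeds the median margin between the two nearest prototypes
(~18). Absolute cross-condition stability is therefore dominated by
exactly the two ingredients that are not publicly specified for the
original implementation — its integrator/encoding internals and five of
the twelve prototype identities — and none of the admissible variants we
tested (priming restricted to the lead-in bars, priming prepended,
cosine distance, frequency-scaled oscillator time constants, stronger
forcing) recovers the absolute levels without breaking the modal-category
or ordering behavior. The shipped defaults were chosen for internal
consistency and kept; users comparing against published absolute agreement
levels should treat those as implementation-specific.

The subharmonic half of classic resonance lore also does not apply in this
regime: for a periodic pulse train of period T, oscillators near 1/T and
2/T are strongly activated, but oscillators near 1/(2T) are *not* elevated
above the bank median — weak forcing through this coupling produces no
subharmonic entrainment. Tests assert the harmonic side only.

## What the synthetic stimuli do and do not capture

All inputs are idealized onset trains: equal-amplitude rectangular pulses
on an exact temporal grid. Real performances vary intensity, timbre and
micro-timing, and listeners hear priming beats as accented; none of that
is modelled. Passing tests therefore show that the dynamical pipeline and
decision rule behave as specified on idealized stimuli, not that the model
predicts human categorization of recorded performances. Problem sizes in
the test suite are the study's own (66 rhythms × 3 conditions ×
145 oscillators × 8 s at 1 kHz), with a reduced 5-oscillator, 200-Hz
configuration for cheap unit-level pipeline checks.
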