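# rhythmcat

A computational model of **categorical rhythm perception** built on neural
resonance: a gradient-frequency network of Hopf oscillators is driven by a
rhythmic onset pattern, and the network's time-summed amplitude response —
its *activation pattern* — is the state on which categorical decisions are
made. The package is for researchers in music cognition and auditory
modelling who want to simulate how short rhythms (1-s patterns of four
onsets) are assigned to integer-ratio notation categories such as 1-1-1 or
1-2-1, and how metric priming (an induced duple or triple beat) shifts those
assignments.

## The model

Each of *n* = 145 oscillators with intrinsic frequency *f_i* (log-spaced
over 0.25–4 Hz, geometrically centered on 1 Hz) evolves independently under
a common scalar stimulus *x*(*t*):

```
dz/dt = z (α + iω + β ε |z|⁴ / (1 − ε |z|²))
        + x / (1 − √ε x) · 1 / (1 − √ε z̄)
```

with ω = 2π *f_i*, damping α = −0.1, amplitude compression β = −0.1 and
scale factor ε = 0.5. An oscillator entrains when the stimulus contains
periodicity near its intrinsic frequency.

From the amplitude trajectories *a_i*(*t*) = |*z_i*(*t*)| the model forms

* the **activation pattern** `A_i = Σ_t a_{i,t}` summed over the second
  half of the trial (the first half is transient),
* the **signal-to-noise ratio** `SNR = A_s / Σ_{i≠s} A_i` with *s* the
  most activated oscillator — a distinctness measure that predicts how
  consistently a rhythm is categorized,
* a **category**: the label of the nearest prototype activation pattern in
  Euclidean state space, where each of the 12 prototypes is the pattern of
  an exact integer-ratio rhythm (e.g. 1-2-1 → IOIs 0.25 s, 0.5 s, 0.25 s).

Stimuli are 8-bar (8-s) trials with the rhythm sounding in bars 3, 5 and 7;
duple/triple conditions add isochronous priming beats in the remaining
bars. The 66-rhythm grid covers the triangular performance space of IOI
triples on a 1/19-s lattice (each IOI ≥ 3/19 s). Agreement between two
category maps is tested with a seeded randomized permutation test
(10,000 label reassignments by default).

## Worked example

```python
import rhythmcat as rc

grid = rc.generate_grid()                 # the 66-rhythm performance space
protos = rc.build_prototypes()            # 12 no-meter prototype patterns
r = rc.RhythmSequence((0.25, 0.5, 0.25))  # a 1-2-1 performance
pat = rc.rhythm_activation(r)             # trial -> stimulus -> bank -> A_i
print(f"rhythms in the performance space: {len(grid)}")
print(f"peak oscillator: {pat.peak_frequency:.3f} Hz")
print(f"SNR: {rc.snr(pat):.4f}")
print(f"category: {rc.classify(pat, protos).display}")
```

prints

```
rhythms in the performance space: 66
peak oscillator: 4.000 Hz
SNR: 0.0302
category: 1-2-1
```

The exact 1-2-1 rhythm is (by construction) classified as its own
prototype; its strongest resonance sits at the 4-Hz edge of the bank,
driven by the rhythm's 4-Hz lattice of onsets, and the SNR of ~0.03 is
about four times the uniform-pattern floor of 1/144 ≈ 0.007.

The same pipelines are available from the shell:

```sh
rhythmcat grid --out grid.csv
rhythmcat snr-map --condition none --out snr.csv
rhythmcat categorize --condition duple --out duple.csv
rhythmcat compare none.csv duple.csv --seed 1
```

Every model stage is configurable through a YAML file (oscillator count and
range, Hopf parameters, pulse encoding, priming-bar layout, activation
window, distance metric, permutation settings); see
`rhythmcat/config.py` for keys and defaults.

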