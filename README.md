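# dyadsync

Automated video analysis of non-verbal coordination in a two-person
(dyadic) interaction — built for medical-encounter research, where the
quality of physician–patient rapport is conveyed largely through body
motion, and human coding of videos is too labor-intensive to scale.

From a fixed-camera recording of two seated interlocutors (or from
precomputed energy series), `dyadsync` computes:

* **motion kinetic energy** per person: dense optical flow between
  consecutive frames, split at a vertical boundary between the two
  people; the energy of a region is the sum of squared pixel velocities
  `E(n) = Σ (u² + v²)`;
* **synchrony** `x = c(0)`: the zero-lag value of the normalized
  cross-correlation of the two energy series,

  `c(τ) = Σₙ Ẽ_S(n+τ) Ẽ_A(n) / ((N−|τ|)·std(E_S)·std(E_A))`,

  where positive lag means the subject moves after the actor;
* **entrainment / followership** `y`: the centre of mass
  `∫ τ c(τ) dτ / ∫ c(τ) dτ` over lags `[−T, T]` — positive when the
  subject follows the actor, near zero when followership is mutual;
* **dominance / turn-taking**: the same centre of mass over a 20 s
  moving window; runs of constant sign form leadership bouts, and the
  ratio of mean subject-led to actor-led bout durations measures
  turn-taking balance;
* **jitter**: spectral power of the energy series at 1.5–5 Hz, a
  kinematic marker of followership;
* **scenario classification**: a bootstrapped logistic classifier
  `P = 1/(1 + a·e^(bx+cy))` separating interaction styles (e.g. an
  engaged, actively listening interviewer vs a disengaged one) in the
  (synchrony, entrainment) plane, with Mann–Whitney / rank-biserial
  group statistics per metric.

A synthetic-dyad generator (energy-level and rendered-video-level) with
known coupling lags, synchrony, and jitter content makes the entire
pipeline testable without access to recordings.

## Worked example

`examples/04_cohort_classifier.py` generates a synthetic cohort of 21
"disengaged" (A) and 22 "engaged" (B) dyads, reduces each to its
metrics, and runs the group-level analysis:

```
group means (A = disengaged, B = engaged):
  synchrony c(0):   A 0.056   B 0.244
  entrainment CoM:  A +1.08 s  B +0.04 s
  subject jitter:   A 0.17   B 1.81
  dominance ratio:  A 0.66   B 1.16
subject jitter A vs B: U=462, p=2.1e-08, rank-biserial r=1.00
classifier P(B) = 1/(1 + a e^(bx+cy)):  a=23.8, b=-23.6, c=0.11
out-of-bag accuracy = 84 ± 9 % (baseline 51 %)
```

Reading the numbers: engaged dyads move together more (higher `c(0)`),
follow each other symmetrically (centre of mass near 0 s, vs +1.1 s of
one-way subject-follows-actor entrainment in A), carry far more
high-frequency jitter, and take turns leading more evenly (dominance
ratio nearer 1). The two features alone let a logistic classifier
identify the scenario of ~84 % of held-out dyads against a 51 % chance
baseline.

The other examples each demonstrate one capability: per-dyad analysis
(`01`), recovery of a known 2 s followership lag (`02`), jitter band
power vs injected jitter amplitude (`03`), and the video stage against
analytic ground truth (`05`). Each prints what it computes and what
the numbers mean.

## Command line

```sh
dyadsync simulate --preset B --n 5 --seed 1 --out-dir sim   # synthetic dyads
dyadsync analyze --input sim/dyad000.csv --out-dir out      # per-dyad pipeline
dyadsync analyze --input frames_dir/ --fps 25 --boundary-col 64 --subject-side left
dyadsync cohort metrics.csv --out report.json --seed 1      # group stats + classifier
```

`analyze` accepts image-sequence directories, imageio-decodable video
files, or energy CSVs (`frame_index,subject_energy,actor_energy` with
the frame rate in a `# fps:` header). Outputs are plain CSV/JSON, each
stamped with the seed and a configuration hash.

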