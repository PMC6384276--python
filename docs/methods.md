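# Methods

This note documents the models, conventions, numerical choices and known
limitations of `vepltp`, in the order the pipeline runs them.

## Synthetic cohorts

### What is emulated

A cohort of participants in the visual sensory-LTP paradigm: three
low-frequency stimulation blocks (pre-tetanus, early post-tetanus, late
post-tetanus), each presenting two grating orientations 240 times at
0.67–1 Hz (33 ms presentation, 1,000–1,500 ms jittered ISI, i.e.
onset-to-onset intervals uniform on [1,033, 1,533] ms), recorded at
1,000 Hz on a 32-channel schematic montage. The tetanus block itself is
not simulated — no evoked response is extracted from it — only its
consequence: a shift of the N1b segment for the tetanized orientation in
the post-tetanus blocks. The default cohort is 10 Val/Val, 10 Val/Met and
8 Met/Met participants with the tetanized orientation counterbalanced to
within one participant.

### Waveform and topography

The VEP template is a sum of two Gaussians: N170 (latency 170 ms,
amplitude −4 µV, width 25 ms) and P2 (240 ms, +3 µV, 40 ms). Gaussian
deflections make all extrema and window integrals analytically known. The
spatial profile is flat-topped: weight exactly 1 on the posterior channels
within 0.5 head-radius of P7/P8 (CP5/P7/P3/PO3 and mirror), Gaussian decay
(width 0.3) outside, then shifted/rescaled to zero spatial mean with unit
plateau gain. Two consequences, both deliberate:

- the signal lives in the common-average space, so offline re-referencing
  leaves the evoked response exactly unchanged (anterior channels carry
  the physiologic polarity inversion);
- every channel a posterior cluster can select has unit gain, so injected
  effects survive cluster averaging without attenuation.

### Effect injection and sign conventions

Per-participant true effects are **waveform shifts** in µV (negative =
potentiation): genotype mean + N(0, participant SD), with late-block
defaults −1.5 (Val/Val), −0.3 (Val/Met), +0.5 (Met/Met — i.e. Met/Met
inverts to depression) and early-block defaults −1.0/−0.1/+0.2. The
downstream LTP *score* is pre − post, so a shift of −1.5 µV is recovered
as a score of +1.5 µV; all statistics and plots use the score convention
(positive = potentiation).

The injected effect is not N170-shaped but a flat-topped bump: value 1
over the N1b window (plus 5 ms of margin on each side) with 30 ms
raised-cosine tapers. This makes the N1b window mean, and the waveform
minimum, shift by exactly the injected amplitude — so noiseless
end-to-end recovery is exact up to filter edge effects (< 0.02 µV
measured, < 0.05 µV asserted). An N170-amplitude-scaled injection would
recover only the window-averaged fraction of the shift and make the
"recovered equals injected" property unattainable.

### Parameter defaults and their provenance

| parameter | default | rationale |
|---|---|---|
| group sizes | 10/10/8 | the study design |
| late effects (shift) | −1.5/−0.3/+0.5 µV | reported ordering, Met/Met inversion |
| early effects (shift) | −1.0/−0.1/+0.2 µV | early pattern: Val/Val strongest, Val/Met ≈ Met/Met |
| participant SD | 0.75 µV | implied by the strongest reported pairwise contrast (BF ≈ 408 at n = 10 vs 8 → d ≈ 2.6 → SD ≈ 2.0/2.6) |
| memory target r | 0.44 | the reported late-LTP/memory correlation |
| memory mean/SD | 75/10 % | plausible WMS-style percent-correct scale |
| noise | 2 µV RMS pink (1/f) noise, 30% shared posterior component | realistic EEG spectra for filter testing |

Memory scores mix the standardized (negated-shift) late-LTP vector with
independent Gaussian noise so the *population* correlation equals the
target, then map to mean 75, SD 10, clipped to [0, 100]. Clipping is rare
at these settings and the induced attenuation is negligible.

`simulate_ltp_table` emits participant-level measured scores directly
(true score + N(0, 0.15 µV) measurement noise — the residual scale left
by averaging ~240 epochs of few-µV background), bypassing the continuous
EEG path for statistics-level studies; the full path is available through
`simulate_cohort().iter_recordings()` and the CLI.

### Randomness

All randomness descends from one seed through fixed `SeedSequence` keys:
`(seed, 0)` cohort structure, `(seed, 1)` memory noise, `(seed, 2, i, b)`
the continuous EEG of participant i in block b, `(seed, 3)` memory-subtest
split, `(seed, 4)` measurement noise. Any participant/block can therefore
be regenerated in isolation, and identical configs give byte-identical
outputs.

### What the simulator does not emulate

Ocular/blink artifacts with realistic morphology (rejection is exercised
with synthetic amplitude spikes), the 8.6 Hz steady-state response during
the tetanus, volume-conduction-realistic channel covariance, drifting
impedances, or a 128-channel geodesic geometry. Passing tests therefore
show that the *analysis* chain is correct and calibrated, not that it is
robust to every pathology of real recordings.

## Preprocessing

Fixed order (enforced and tested): common-average re-reference →
band-pass filter → epoching → baseline correction → artifact rejection →
block averaging.

- **Filter**: three-pole Butterworth band-pass 0.1–30 Hz, applied forward
  and backward (zero phase, squared magnitude response). Reflection
  padding spans three time constants of the low cutoff (3·fs/low_hz
  samples, clamped to the data length): the slowest pole of the 0.1 Hz
  high-pass decays with τ ≈ 3.2 s, and shorter padding leaves visible
  edge transients.
- **Epochs**: half-open [−100, 500) ms, sample-aligned to onset (onset
  sample counted post-stimulus), so 600 samples at 1 kHz exactly. Markers
  too close to an edge drop their epoch with a logged warning.
- **Baseline**: per-epoch, per-channel mean over [−100, 0) ms subtracted.
- **Artifact handling**: the conventional reproducible substitute for
  blink handling — peak-to-peak threshold rejection (default 150 µV on
  the worst channel), plus optional regression of a designated EOG-like
  channel (`regress_out_eog`) when one exists. Default path rejects
  rather than corrects. All-rejected cells are legal but loudly reported.
- **Averaging**: arithmetic mean over kept epochs per block × condition.

The whole chain is linear in the data (rejection thresholds held
proportional), which the suite verifies.

## Component quantification

Clusters: per hemisphere, the k = 4 posterior channels (y < −0.1, x on the
matching side; midline channels belong to neither hemisphere) with the
most negative mean amplitude in the N170 search window of the grand mean
over all six block × condition cells; ties resolve by channel order.
Peaks: N170 = cluster-mean minimum in 130–220 ms, P2 = maximum in
(N170+10, 320) ms, ties to the earliest sample, extrema on a window edge
flagged rather than rejected. The search windows bracket canonical
latencies and are config-overridable. Peaks are detected on the
pre-tetanus block (both conditions averaged) and the resulting N1b window
[t(N170), midpoint(t(N170), t(P2))] is held fixed across blocks, avoiding
window-shift confounds; windows shorter than 1 ms are rejected as
degenerate. Amplitudes pool both hemispheres' clusters and average all
samples inside the window, endpoints included.

## Bayesian battery

All Bayes factors are one-dimensional integrals evaluated with adaptive
quadrature (relative tolerance 1e-8; the reported `integration_error` is
the quadrature's own estimate). No posterior sampling is involved: the
model comparisons only need marginal likelihoods, and quadrature makes
them exact, fast and testable. Monte-Carlo versions of every integral
(`mc_*`, sampling the mixing variable g or prior draws of ρ) serve as
independent oracles and agree within 0.5% in the suite.

Parameterizations:

- regression: Zellner–Siow mixture g-prior, g ~ InvGamma(½, n·r²/2),
  r scale 0.354;
- ANOVA: g-prior on standardized sum-to-zero projected group effects,
  g ~ InvGamma(½, r²/2), r scale 0.5. For two balanced groups this
  reduces exactly to the t test at scale r·√2 (verified in the suite).
  Fully degenerate data (zero total variance) carry no effect
  information; the likelihood ratio is taken as 1 and the determinant
  penalty keeps BF₁₀ < 1;
- t test: the standard JZS form in the t statistic, g ~ InvGamma(½, r²/2),
  r scale 0.701;
- correlation: stretched-beta prior on ρ with width κ, two-sided,
  integrating the reduced likelihood of the sample r (location and scale
  integrated out); a hypergeometric closed form cross-checks the
  quadrature. **Default κ = 1 (uniform prior on ρ).** The conventional
  "medium" κ = 1/3 yields BF(r = 0.44, n = 28) ≈ 4.10 and
  BF(0.02, 28) ≈ 0.41, incompatible with the reported 3.32 / 0.24;
  κ = 1 yields 3.20 / 0.24, and at the unrounded r ≈ 0.4427 (the value
  that also makes the regression BF print 3.27 with P(M|data) = 0.77)
  it reproduces 3.32 exactly. The width is an argument everywhere.

Rounding for reports: BFs and probabilities to two decimals; posterior
probabilities above .99 print as "> 0.99".

### Numerical caveat: rounded inputs

Bayes factors recomputed from two-decimal printed statistics (r = 0.44)
differ from those computed on raw data in the second decimal: the
regression BF evaluates to 3.17 (vs 3.27 unrounded) and the correlation
BF to 3.20 (vs 3.32), while r = 0.02 → 0.24 is stable. This is input
rounding, not integration error; the quadrature is accurate to ~1e-8.

### Calibration of the qualitative pattern

Under the default generator (ρ = 0.44, n = 28, group effects above), the
probability that a single cohort shows the full qualitative pattern —
late-LTP regression BF > 1, genotype ANOVA BF > 1, Val/Val vs Met/Met the
strongest pairwise contrast — is ≈ 0.73 (measured over 400 seeded
cohorts: regression leg 0.77, ANOVA leg 1.00, ordering leg 0.94). The
regression leg is the ceiling: the sampling distribution of r at ρ = 0.44,
n = 28 falls below the BF = 1 threshold (r* ≈ 0.314) in roughly 22% of
cohorts, and no noise-parameter choice can raise that without changing
the target correlation or the sample size. A single n = 28 study of this
effect is, in other words, underpowered for the regression claim — a
conclusion the simulation machinery here makes quantitative.

## The Model/Results interface

`LTPMemoryModel.from_dataframe(table)` takes the participant-level table
(genotype, early/late LTP scores, memory index); `fit()` runs the full
battery (2 regressions, 2 correlations, 3 ANOVAs, 9 pairwise contrasts)
and returns an `LTPMemoryResults` with `summary()`, `to_frame()`,
`to_json()`, `largest_pairwise()`, and plotting helpers. The pipeline's
`analyze` stage is this object; the CLI and `run_pipeline` are thin
wrappers.

## Problem sizes used by the test suite

The suite exercises the continuous-EEG path at desk scale — cohorts of
3–6 participants, 6–30 presentations per orientation — which is
sufficient because the noiseless-recovery and linearity properties are
size-independent; statistical calibration runs on the participant-level
generator (200 cohorts of 28). Monte-Carlo oracles use 10⁶–10⁷ draws.

## Known limitations

- No ICA, bad-channel interpolation or source modelling; the artifact
  model is a threshold plus optional EOG regression.
- The ANOVA is fixed-effects one-way only; no random/mixed designs, no
  parameter estimation or credible intervals.
- EDF export is not provided (no EDF writer in the dependency set);
  recordings persist to a documented HDF5 layout.
- The montage is schematic 2-D; cluster selection is montage-agnostic but
  geodesic-net geometry is not reproduced.
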