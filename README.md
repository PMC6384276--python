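# vepltp

Sensory long-term potentiation (LTP) of the human visual evoked potential
(VEP), end to end: synthetic genotype-structured EEG cohorts, the standard
preprocessing chain, peak-anchored N1b quantification, and a default-prior
Bayesian statistical battery — for researchers studying non-invasive
plasticity paradigms and their relation to memory.

## The problem

Rapid ("tetanic", ~9 Hz) visual stimulation induces an enduring negative
shift of the N1b segment of the VEP — an LTP-like form of experience-
dependent plasticity measurable non-invasively with EEG. Two questions
drive the analysis this package implements:

1. Does the magnitude of that potentiation predict visual long-term memory
   performance (a WMS-III-style recognition index)?
2. Is the potentiation modulated by the *BDNF* Val66Met polymorphism
   (genotypes Val/Val, Val/Met, Met/Met)?

Because no public data accompany this paradigm, the package ships a
first-class simulator: it generates continuous 1,000 Hz multi-channel
recordings with posterior-maximal VEPs (N170 + P2 deflections), three
low-frequency blocks (pre-tetanus, early post-tetanus ~0 min, late
post-tetanus ~40 min) of 240 presentations per grating orientation,
genotype-dependent N1b shifts for the tetanized orientation only, pink-
noise background, and memory scores correlated with late potentiation at a
configurable target (default r = 0.44).

## The measurements and the statistics

**N1b quantification.** Per participant, posterior electrode clusters
(k = 4 per hemisphere, anchored near P7/P8) are chosen from the
all-condition grand mean; the N170 peak (cluster-mean minimum in
130–220 ms) and P2 peak (maximum thereafter) define the N1b window
[t(N170), (t(N170) + t(P2))/2]. LTP scores are pre-minus-post N1b mean
amplitude, so potentiation (a more negative post-tetanus N1b) is positive:

    early LTP = A(pre) − A(early post),   late LTP = A(pre) − A(late post)

The identical computation on the non-tetanized orientation is always
emitted as a specificity control.

**Bayes factors** (all by deterministic quadrature, tolerance 1e-8):

- one-predictor JZS regression from (n, R²):
  BF₁₀ = ∫ (1+g)^{(n−p−1)/2} [1+g(1−R²)]^{−(n−1)/2} π(g) dg,
  g ~ InvGamma(½, n·r²/2), default r scale 0.354;
- two-sided default correlation test with a stretched-beta prior of width
  κ on ρ (default κ = 1, i.e. uniform), integrating the reduced likelihood
  of the observed r;
- one-way fixed-effects ANOVA with a g-prior on standardized sum-to-zero
  group effects, g ~ InvGamma(½, r²/2), default r scale 0.5;
- two-sample JZS t test, default r scale 0.701;
- conversions P(M|data) = BF/(1+BF) and BF_M (prior-to-posterior odds).

Every quadrature has an independent Monte-Carlo oracle
(`vepltp.bayes.mc_*`) used by the test suite.

## Worked example

```python
from vepltp import SimulationConfig, simulate_ltp_table, LTPMemoryModel

table = simulate_ltp_table(SimulationConfig(seed=7))   # 28 participants
results = LTPMemoryModel.from_dataframe(table).fit()
print(results.summary())
```

prints (abridged):

```
LTP-memory Bayesian battery
============================================================
Participants: n = 28

Group means
------------------------------------------------------------
  late LTP           Val/Val: 1.70, Val/Met: 0.42, Met/Met: -0.77
  ...
LTP as a predictor of memory
------------------------------------------------------------
  late LTP   regression (r scale 0.354): P(M|data) = 0.71, BF_M = 2.45
  late LTP   correlation r = 0.42, BF10 = 2.38
  early LTP  regression (r scale 0.354): P(M|data) = 0.28, BF_M = 0.40
  ...
Genotype effects
------------------------------------------------------------
  ANOVA on late LTP (r scale 0.50): P(M|data) = > 0.99, BF_M = 367689.38
      Val/Val vs Val/Met: BF10 = 155.12
      Val/Val vs Met/Met: BF10 = 59041.16
      Val/Met vs Met/Met: BF10 = 32.44
```

Reading it: late potentiation is largest in Val/Val homozygotes, inverts
(depression) in Met/Met, predicts the memory index with moderate evidence
(BF ≈ 2–3 at n = 28), and separates the genotype groups decisively — the
qualitative pattern the paradigm is designed to detect. `simulate_ltp_table`
gives participant-level scores directly; the full continuous-EEG route is

```bash
vepltp run-all --seed 7 --out results_dir     # simulate → preprocess →
                                              # quantify → analyze → report
```

which writes `participants.csv`, `measurements.csv`, `ltp_scores.csv`,
`stats.json`, `report.md` and a run log with the config hash.

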