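# Methods

`hvcseq` reimplements, as a tested pipeline, the unsupervised analysis used
to discover, validate, quantify, and track neural sequences in calcium
imaging recordings from the songbird premotor nucleus HVC. This note
documents the models, the statistical procedures, the defaults, and the
choices made where the design was genuinely open.

## The data model

The universal input is a neurons × timebins matrix recorded at a fixed
frame rate (default 30 Hz), concatenated from many short (~10 s) recording
files ("segments" or bouts — recordings are made only while the bird
sings). Files are independent: nothing in the pipeline is allowed to
correlate activity across a file boundary.

## Preprocessing: AR-2 deconvolution and renormalization

Fluorescence is modelled per neuron as an AR(2) process driven by
non-negative neural events plus white observation noise:

    y_t = c_t + e_t,    c_t = γ1 c_{t-1} + γ2 c_{t-2} + s_t,    s_t ≥ 0.

The default kernel (γ1, γ2) = (1.4, −0.45) has poles 0.9 and 0.5 at 30 Hz,
i.e. a GCaMP6f-like ~0.3 s decay and fast rise.

**Parameter estimation.** Both poles, the drive variance, and the noise
variance are fit per neuron by minimizing the Whittle likelihood of the
trace periodogram under the spectrum `S(ω) = σs²/|1 − γ1 e^{−iω} −
γ2 e^{−2iω}|² + σn²`. The poles are parametrized through a sigmoid so the
estimate is stable by construction. This spectral fit proved markedly more
accurate than moment-based (Yule–Walker) estimation on sparse-event traces
(±0.03 vs ±0.10 on the AR coefficients at 10⁴ samples). One caveat the
tests document: when the driving events are sequence-structured rather than
Poisson, the drive is not spectrally white (events within a factor keep a
minimum separation), which biases the kernel estimate by a few percent;
this is a property of the data, not the estimator, and is immaterial for
event detection.

**Deconvolution.** Events are recovered by the exact AR-2 inverse filter
`s_t = y_t − γ1 y_{t−1} − γ2 y_{t−2}`, clipped at zero, with two
suppression rules that control sparsity: values below 4 noise-sd
(propagated through the inverse filter, with a robust MAD guard against
degenerate noise-floor estimates) are zeroed, as are values below 3% of the
row maximum (sub-percent ringing left by small kernel-estimate errors).
Each file is deconvolved independently. Any solver meeting the
"non-negative events whose reconvolution approximates the trace" contract
would do; this one is exact on noiseless data and reaches event-detection
F1 ≈ 0.97 on low-noise simulations.

**Renormalization.** Each neuron's event series is divided by (its own
maximum + the 95th percentile of the whole deconvolved matrix, zeros
included). Strongly expressing neurons keep some priority but not much more
than weak ones. The rule is scale-covariant and deliberately not
idempotent. The global percentile is computed on the deconvolved signal
(the most literal reading of the rule; computing it on raw fluorescence is
the main alternative and would only change the common denominator).

## Convolutional NMF

The factorization model is X ≈ W ⊛ H with W a neurons × K × L non-negative
exemplar tensor (L = 0.5 s by default) and H a K × T non-negative
occurrence timecourse:

    X̂[n, t] = Σ_k Σ_ℓ W[n, k, ℓ] H[k, t − ℓ].

Fitting minimizes ‖X − X̂‖²_F + λ·R by multiplicative updates, where R is
the cross-orthogonality penalty Σ_{k≠k'} [(Wᵀ⊛X) S Hᵀ]_{kk'} with S a
boxcar of width 2L−1: factor pairs whose data-projected, smoothed
timecourses correlate are charged, which suppresses redundant copies of a
sequence when K is set too high. ε = 1e−10 is added to update denominators.

Numerical choices:

- H is masked to zero within L bins of each file end, so occurrences cannot
  convolve across independent recordings.
- Multiplicative updates for this penalty are heuristic, not provably
  monotone. A backtracking safeguard keeps the recorded cost history
  non-increasing: if an iteration raises the penalized cost, the iterate is
  interpolated halfway back toward the previous one (up to three times) and
  fitting stops if no interpolation helps. In practice backtracking almost
  never triggers.
- Convergence is declared after the relative cost change stays below 1e−6
  for five consecutive iterations; multiplicative updates stall on saddle
  plateaus for a few iterations before escaping, so a single-iteration
  criterion stops too early.
- Default 100 iterations; the heavier resampling loops use 40–80.

**Power explained** is 1 − ‖X − X̂‖²/‖X‖², floored at zero.

**Sequenciness** is 1 − (mean power explained on timebin-shuffled data) /
(power explained on the real data), clipped to [0, 1]; shuffles permute
columns within each file and the shuffled fits restart from the same seed
(10 shuffles by default; projecting fixed W onto shuffled data is exposed
as an option). Zero means all explanatory power is synchronous (it survives
column shuffling); one means all of it is temporally extended. The score is
meaningful on the deconvolved event matrix — on raw, kernel-smoothed
fluorescence a column shuffle leaves much more power explainable and the
upper anchor is unreachable. On structureless data (near-zero power
explained) the score is unstable and the implementation raises instead of
reporting it.

## Choosing λ, K, and a factorization

**λ sweep.** Fits at K = 10, L = 0.5 s across a log-spaced grid (default
1e−4…1, 9 points). Reconstruction cost rises with λ, redundancy cost falls;
both are min-max normalized over the sweep and λ0 is the crossover,
log-interpolated between the bracketing grid points. (On clean synthetic
data the literal "first grid point past the crossing" lands on the cliff
where the factorization collapses to zero; interpolation keeps λ0 in the
stable regime and is the closer reading of a "cross-over point".)

**Counting significant sequences.** Whole files are split 75%/25% into
train/test (seeded random split). Factors are fit on the training set; each
factor is scored by the skewness of its held-out projection Wᵀ⊛X_test — a
sequence that recurs in unseen data produces a sparse, strongly
right-skewed projection. The null distribution shifts each neuron's lag
profile of W circularly by a random amount (≥ 500 draws; the rank p-value
needs at least K/α nulls to resolve the Bonferroni level α/K, and the
implementation warns otherwise). Factors whose training timecourse is empty
(e.g. emptied by the penalty) have no sequence to test and get p = 1.
Factor counts are computed at λ0 and 2λ0 over several seeded splits; the
estimate of K is the midpoint of the two modal counts, rounded half-down
(modes 2 and 3 give 2).

**Consistency.** The final factorization is chosen from 25 random restarts
at the estimated K: pairwise similarity is the mean correlation of greedily
matched, boxcar-smoothed (2L−1) H timecourses, and the run with the highest
median similarity to the others wins. Setting K above the estimated value
visibly disrupts consistency, which the tests verify.

## Circular-shift significance testing

All time-lagged correlation claims use one procedure: zero-mean both
series, compute the circular cross-correlation at every lag, treat lags
with L < |ℓ| < T − L as the null set, and call a lag in [−L, L] significant
when |cc| exceeds the 100×(1 − p/Num)-th percentile of the absolute null
values, with Num = 2L × (number of tests run) — a Bonferroni correction
over the whole family. The comparison is two-sided on |cc| (one-sided is
exposed as an option). Two known finite-size properties, documented rather
than patched: (i) with short series the null set is too small to estimate
the extreme percentile and the test becomes optimistic — at the ~100 s
session lengths used here calibration is nominal; (ii) for an exactly
periodic series the null lags contain the same peaks as lag 0, so nothing
can reach significance — real (jittered) rhythmicity does not have this
degeneracy.

Applications:

- **Participation**: neuron n joins factor k if its trace has any
  significant lag against H[k] with L = 0.5 s and Num = (2L bins) × N × K
  (30 × N × K at 30 Hz).
- **Song locking**: H is upsampled to 1 ms by zero-order hold (preserves
  non-negativity and mass timing) and tested against each of the 8 acoustic
  features with L = 1 s and Num = 2000 × 8 × K; locking is the total
  significant lag time in seconds summed over features.
- **Autocorrelation**: each H row against itself with lags |ℓ| < L_exemplar
  excluded (self-overlap there is trivially significant); the summary is
  integrated significant seconds, a measure of rhythmic production.

## Occurrences, coverage, reliability, specificity, abnormalities

**Occurrence detection** thresholds the projection H̃ = Wᵀ⊛X at the
Bonferroni-corrected 95th percentile (percentile 100×(1−0.05/Num), Num =
K × T by default, configurable) of projections of per-neuron circularly
shifted data (20 shuffles). Supra-threshold runs closer than L/2 bins merge
(projection peaks are exemplar-broad); each occurrence covers its
supra-threshold span extended by the exemplar length.

**Coverage** is the percentage of a bout's bins covered by at least one
factor's occurrences; monotone under adding occurrences.

**Reliability** of a participating neuron is the fraction of its factor's
occurrences at which it emits an event within ±3 bins of its preferred lag
(the lag maximizing its average activity across renditions); undefined for
factors with fewer than 5 occurrences. The window and event criterion
(5% of the row maximum by default) are free parameters the source protocol
does not pin down; both are exposed. On simulations it recovers the planted
participation probability to within ±0.01.

**Sequence specificity** is the fraction of a participating neuron's summed
deconvolved activity falling inside its factors' covered spans.

**Persistent activity** is an abnormality detector: intervals of ≥ 0.5 s
throughout which ≥ 3 of the *same* neurons stay continuously active
(binarized after 2-bin dilation). Requiring the same neurons is what
distinguishes pathological plateau activity from a dense but normal
sequence of brief staggered bursts. **Truncation variability** is the
coefficient of variation of occurrence durations per factor.

## Tracking across days

With neuron identities matched across days (by upstream spatial
registration, outside this package's scope), an exemplar learned on one
day is projected onto another day's data after mean-subtracting both along
time: H̃₂ = Wᵀ⊛X₂, and the exemplar is re-estimated there as W̃₂ = X₂⊛H̃₂ᵀ.
Per-neuron participation on the target day compares W̃₂ against the same
quantity from controls in which every neuron's data is circularly shifted
by a different random amount, at p = 0.05 Bonferroni-corrected for neurons
× lags. One normalization was required beyond the published recipe: W̃₂ is
divided by ‖H̃₂‖ (per factor) so that real and shuffled-control estimates
are on a common scale — the real projection has systematically larger
variance than shuffled projections, and without the normalization every
neuron trivially exceeds the null.

**Sequence persistence** is the Pearson correlation between the flattened
pre- and post-exemplars over matched neurons (exemplars, rather than
timecourses, because the two days' time axes are not comparable), tested
against two nulls of ≥ 1000 draws each: circularly shifting each neuron's
lag profile (destroys order, keeps per-neuron mass) and permuting neuron
rows. Near-synchronous populations weaken the neuron-shuffle null, which
the statistics reflect as an inflated p_neuron. A locking trajectory —
song locking of the projected timecourse on each day — quantifies a
latent sequence becoming coupled to vocal output.

## The synthetic-data generator

The generator emulates the statistical structure of the real recordings so
every stage is testable without data downloads: K planted sequences of
single-bin transients at fixed per-neuron lags (default 2 factors × 30
neurons, 15 ms lag spacing ⇒ ~0.45 s sequences), Bernoulli participation
(default 0.7), Gaussian temporal jitter (10 ms), occasional truncation at a
uniform random fraction (truncation at fraction f silences all neurons
whose lag exceeds f × the maximum lag), persistent-activity episodes (≥ 3
neurons driven continuously ≥ 0.5 s), per-neuron Poisson background events,
lognormal event amplitudes (σ = 0.3, motivating the renormalization stage),
AR-2 convolution per file, additive Gaussian noise clipped at zero, ten
10 s files at 30 Hz, and 8 song-feature channels at 1 ms built as
Gaussian-smoothed mixtures of occurrence indicators and white noise with
per-factor coupling in [0, 1]. Occurrence rate defaults to 0.3 Hz per
factor — a few renditions per file, matching sparse juvenile singing.
Everything planted is returned as ground truth.

Named presets freeze the study conditions used by the tests:
`pure_sequences` (noise-free, full participation), `pure_synchrony` (all
lags collapse to one bin), `noise_only` (no factors, 0.2 Hz background),
`isolate_like` (truncation 0.5, persistent episodes, participation 0.7),
and `learner_like` (two days with matched neurons; factor 1's song coupling
rises 0.1 → 0.8).

What the generator does *not* emulate — and hence what passing tests do not
show about real data: realistic acoustic spectra (features are abstract
coupled channels), cell-extraction artifacts and cross-day registration
errors (identities are exact), neuropil contamination, non-stationary
rates, or bursting with multiple events per sequence rendition. Truncation
and persistent-episode statistics are free parameters of the generator, not
calibrated claims.

## Problem sizes and replication counts

The validation suite runs desk-scale: 60-neuron, 3000-bin sessions; 20
replicate datasets for sequence-count recovery (sharing one λ0 swept on the
first replicate, since the replicates are draws of the same generative
process); 3 seeded splits per λ in K estimation with 250 nulls (500 in the
type-I studies, where the rank p-value resolution matters); 1000
white-noise pairs for family-wise error; 20 two-day datasets for tracking.
These sizes make the full validation reproducible in minutes on one CPU
while keeping every statistical conclusion inside its stated tolerance.

## Known limitations

- The multiplicative updates offer no global-optimality guarantee;
  consistency across restarts is the (published) mitigation.
- λ0 on very clean data sits close to the collapse cliff; the interpolated
  crossover mitigates but K estimation at 2λ0 remains the most fragile
  stage.
- The circular-shift test family is calibrated for series much longer than
  2L; applying it to very short series overstates significance.
- Kernel estimation assumes spectrally white event drive; strongly
  structured drive biases the poles by a few percent.
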