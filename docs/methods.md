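# Methods

This note documents the models, numerical choices and limitations behind
`lungscreen`. It describes what the code does and why; every empirical
number quoted here is computed by the test suite or by
`scripts/acceptance.py`.

## Signal model and preprocessing

Chest-wall lung-sound conduction is treated as band-limited to 80–1000 Hz.
The working sample rate is 4000 Hz: it is the smallest round rate whose
Nyquist frequency clears the upper band edge and whose 6 s segments
(24 000 samples) still support a 10-level db7 wavelet decomposition
(db7 has filter length 14; `pywt.dwt_max_level(24000, 14) = 10`).
Recordings at other rates are polyphase-resampled on load; multichannel
audio is averaged to mono. WAV with 16-bit PCM is the default interchange
format (floats are accepted on read), so a save/load round trip is exact in
rate and within one quantization step (2⁻¹⁵) in amplitude.

The bandpass is a cascade of an order-5 high-pass at 80 Hz and an order-5
low-pass at 1000 Hz rather than a single bandpass prototype. Two
consequences worth knowing:

* **Zero-phase application.** Filtering is forward–backward
  (`sosfiltfilt`), which cancels group delay but squares the magnitude
  response: the designed −3 dB cutoffs become −6 dB points of the applied
  response. The −3 dB cutoff checks in the tests therefore probe the
  designed (single-pass) response.
* **Compounded ripple in the comparison families.** For Chebyshev type 1
  (default 1 dB ripple) both cascade sections ripple across the shared
  passband, so the observed peak-to-trough oscillation of the cascade is of
  order 1–2 dB, not the single-section 1 dB. The Butterworth cascade stays
  maximally flat (no interior ripple extrema), which is the property that
  motivates its selection. Chebyshev stopband attenuation defaults to
  40 dB; both parameters are configurable.

Processing order is filter → normalize → segment. Normalization divides by
the peak magnitude per *recording* (not per segment), so relative segment
amplitudes within a recording are preserved; the choice matters only for
amplitude-sensitive features and is fixed in the config. Segments are
consecutive, non-overlapping, exactly 6 s; a trailing remainder is
discarded, and recordings shorter than one segment are rejected.

Power spectra are one-sided rectangular-window periodograms normalized so
that the sum of the power values equals the signal's mean square (discrete
Parseval convention); the window is selectable but the default keeps the
entropy computation free of window-choice effects.

## Features

Thirteen features per segment, in canonical order: `Entropy`,
`Spec.Entropy`, `RMScA`, `RMScD1` … `RMScD10`.

* **Shannon entropy** is computed on the amplitude distribution of the raw
  (pre-wavelet) segment. Amplitudes are discretized on 256 equal-width bins
  over [−1, 1] — an 8-bit quantization that keeps the histogram estimate
  stable for 24 000-sample segments; the bin count is configurable. The
  entropy is unnormalized, in bits, bounded by log₂ 256 = 8.
* **Spectral entropy** is the Shannon entropy of the periodogram normalized
  to unit sum over its one-sided grid (per-bin, not banded). For a 24 000
  sample segment the grid has 12 001 bins, so white noise approaches
  log₂ 12 001 ≈ 13.55 bits while a pure tone approaches 0. A zero-power
  segment has no distribution to measure and raises a degenerate-input
  error.
* **RMS features** are √(Σ D²/N) of each coefficient set of the 10-level
  db7 decomposition with symmetric boundary extension (the common
  convention for feature extraction). Periodized extension — under which
  the transform is exactly orthogonal on dyadic-divisible lengths — is used
  only by the energy-conservation test.

Feature extraction is a pure function; scaling a segment by c scales every
RMS feature by |c| and leaves the spectral entropy unchanged.

## Feature selection

The Kruskal–Wallis statistic is implemented literally as
H = 12/(N(N+1)) Σ Rᵢ²/nᵢ − 3(N+1) with midranks for ties and **no**
tie-correction divisor by default; the conventional correction
1 − ΣT/(N³−N) is available behind a flag (and is what `scipy.stats.kruskal`
always applies — the tests use that as a cross-check of the corrected
variant). A feature is accepted when H exceeds the upper-tail chi-squared
critical value at k−1 degrees of freedom, α = 0.05 by default. Ranking
ties in H are broken by canonical feature order so the ranking is invariant
to row permutation.

The incremental evaluation trains the classifier on the top-m features for
m = 1…13 with one shared stratified split and seed, so the accuracy curve
is comparable across m; the selected subset is the argmax of test accuracy
with ties broken toward the smaller subset. When a user skips selection on
their own data, a 10-feature default subset (Entropy, RMScD9, Spec.Entropy,
RMScD10, RMScD3, RMScD2, RMScD4, RMScD8, RMScA, RMScD5) is exposed as
`selection.DEFAULT_SELECTED_FEATURES`.

## Classifier

A single-hidden-layer feed-forward network: ReLU hidden layer (default 250
nodes), softmax output over the four classes, categorical cross-entropy
plus an L2 penalty on the weight matrices. It is implemented directly on
numpy, which keeps training exactly reproducible from a single seed
(initialization, batch order, dropout masks and the validation split all
derive from one generator).

Hyperparameter defaults, all configurable: dropout 0.3 (inverted, hidden
layer, training only), L2 penalty 10⁻⁴, Adam with step 10⁻³, batch 32,
validation fraction 0.1, early-stopping patience 50 epochs with
best-weight restoration, maximum 1000 epochs. He-scaled Gaussian
initialization. Features are z-scored with training-split statistics that
travel with the model. Inputs to training are stratified-split 80:20 and
the training split is oversampled (with replacement) to class balance —
oversampling rather than undersampling so scarce classes are not discarded.

Determinism is promised at the bit level only within a fixed platform and
BLAS; across platforms, accuracy metrics (not weights) are expected to
match.

The hidden-node sweep trains one model per width on a shared split and
selects, among the widths whose test accuracy is within 0.01 of the best,
the one with the smallest train–test gap (ties toward fewer nodes) — the
"highest accuracy with the smallest generalization gap" rule.

## Evaluation conventions

One-vs-rest reductions of the 4×4 confusion matrix give per-class
sensitivity, specificity and precision; overall accuracy is trace over
total; macro metrics are unweighted class means. A zero denominator raises
an error naming the class and metric instead of silently reporting 0, so
degenerate evaluation sets are visible.

Screening reports render probabilities as percentages rounded to two
decimals; group aggregates are the arithmetic mean and the **population**
standard deviation (divisor n) of the rounded percentages, themselves
rounded to two decimals. The population form is the one consistent with
recomputing the reference mean/SD rows from their printed per-row inputs.

## Synthetic corpus

The generator produces what the downstream stages need to be testable:
labeled, seeded recordings whose class differences live in the same
acoustic dimensions the features measure.

* **Healthy**: Gaussian noise band-limited to 80–1000 Hz, amplitude-
  modulated by a raised-cosine inspiration/expiration envelope (default
  4 s cycle: 40% inspiration, 45% expiration at 0.7 relative gain, floor
  0.05), so every 6 s segment spans at least one cycle.
* **Pneumonia**: healthy plus exponentially damped sinusoid crackles
  (200–600 Hz centers, 5–15 ms, Poisson-placed in inspiratory phases).
  Defaults are 20 crackles per cycle at 8× the breath RMS: pneumonia
  crackles are dense, clearly audible transients, and global RMS/entropy
  features — unlike dedicated transient detectors — only register them at
  realistic loudness and density.
* **COPD**: healthy plus sustained tonal wheezes (default 150 and 400 Hz)
  gated to expiratory phases at 2× breath RMS.
* **Other**: a distributional mixture standing in for the pooled residual
  disease class — slowed cycle (×1.3–1.7), narrowed noise band, faint
  low-frequency wheeze — distinct from the three named classes without
  being a fifth acoustic archetype.

Broadband sensor noise is added at a configurable SNR (default 10 dB), and
the result is scaled to 0.9 peak so 16-bit PCM round trips without
clipping. All per-recording seeds are spawned deterministically from the
corpus seed.

What the generator does **not** emulate: real airway acoustics (no
physiological model), inter-patient variability, recording-device and
environment diversity, coughs/speech/handling artifacts, or the extreme
class imbalance of real screening corpora. Passing the parameter-recovery
check (held-out accuracy ≥ 0.90 on 40 recordings per class at 10 dB SNR)
therefore demonstrates that the pipeline's stages compose correctly and can
recover class structure that is present in its feature space — not that
comparable accuracy would be reached on clinical recordings.

## Problem sizes

The reference corpus for parameter recovery is 40 recordings per class,
12 s each (two 6 s segments), i.e. 320 feature rows — large enough for the
rank test and the network to be well-conditioned while keeping a full run
in seconds. The greedy feature curve and the node sweep in the test suite
run on a 10-recording-per-class corpus with a reduced network (16–64 hidden
nodes, no dropout, fixed epochs), which exercises the procedures' contracts
without the cost of the full configuration; `scripts/acceptance.py` runs
the sweep at the full 200–300-node widths.

## Known limitations

* The entropy discretization (256 bins) and the per-bin spectral-entropy
  convention are fixed choices among several defensible ones; both are
  configurable, and ranked H-values shift somewhat with them.
* Exact training determinism is platform-scoped (see above).
* The "other" class is a synthetic stand-in for a heterogeneous pool; its
  separability in the synthetic corpus is by construction and says nothing
  about the real pooled class.
* Undefined metrics raise; pipelines aggregating many small evaluation sets
  should catch `UndefinedMetricError` explicitly.
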