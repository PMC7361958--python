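# Methods

## Pipeline model

`eegdx` treats disorder screening as segment classification. A recording
(single-channel plain text at a nominal 173.61 Hz, or multi-channel EDF at
an integer rate such as 256 Hz) is cleaned, cut into fixed windows, band
limited, decomposed into wavelet sub-bands, summarized by per-band
statistics, and classified. Nothing in the pipeline uses temporal context
across segments; each segment is an independent observation, and
cross-validation treats it as such (a group-aware folding mode exists for
the stricter per-subject regime — see *Cross-validation*).

## Segmentation

Windows are non-overlapping and default to 50 s. Plain-text signals of the
common ~23.6 s single-channel sets are shorter than one window; the default
tail policy `whole-if-shorter` therefore returns one flagged segment
covering the whole recording, so short recordings remain usable without
changing the nominal window. `drop` and `keep-short` are selectable. A
segment must contain at least 2⁴ × (filter length) samples (128 for db4)
for the level-4 decomposition to be defined.

## Filtering

The band-pass is an elliptic (Cauer) IIR design: band 0.1–60 Hz, order 8,
0.5 dB passband ripple, 40 dB stopband attenuation. Order, ripple and
attenuation are conventional EEG values and all overridable; the band is
the pipeline's fixed analysis band. An optional 60 Hz notch is off by
default, since at a 173.61 Hz sampling rate 60 Hz sits at the band edge.

**Zero-phase application.** Features downstream are spectral statistics, so
the default application is zero-phase. The textbook route — forward-backward
time-domain filtering (`filtfilt`) — is numerically unusable here: the
0.1 Hz lower band edge places poles at radius ≈ 0.99998, whose transients
decay over minutes, and on 8–50 s segments those edge transients dominate
the output (an 80 Hz probe tone came through at ~27 % RMS instead of the
designed −80 dB). Zero-phase mode therefore multiplies each channel's
spectrum by the realized filter's squared magnitude response |H(f)|² —
exactly what forward-backward filtering converges to on an infinite signal,
without the transient. Consequences to keep in mind:

- the effective passband ripple is twice the design ripple in dB (as with
  `filtfilt`);
- the operation is circular in the segment; for band-limited EEG content
  this wrap-around is negligible, and the contract tests (tone attenuation,
  linearity, zero group delay) all measure the realized behaviour.

`causal` mode applies the IIR filter once in the time domain, for users who
need a strictly causal path.

## Ocular artifact removal

Multi-channel recordings with designated EOG reference channels are cleaned
by FastICA over the non-EOG channels (as many components as channels,
deterministic per seed, one retry with a fresh seed on non-convergence).
A component is deemed ocular when its absolute Pearson correlation with any
EOG reference exceeds the threshold (default 0.7); ocular components are
zeroed before reconstruction, and EOG channels are dropped from the output.
Single-channel recordings pass through unchanged — ICA is undefined there —
as do recordings without EOG references (the report says why). Adaptive
(LMS/RLS) cancellation is deliberately not implemented.

## Wavelet decomposition

Four-level DWT with db4. Boundary handling defaults to periodic orthonormal
extension, which makes the transform orthogonal: total coefficient energy
equals signal energy and the inverse reproduces the input, both checked to
1e-8 relative in the test suite. Symmetric extension is selectable for
users who prefer its boundary behaviour over exact orthogonality.

Sub-band nominal frequency ranges are derived from the actual sampling rate
by successive halving of the Nyquist interval — D1 = (fs/4, fs/2], halving
down to A4 = (0, fs/32] — rather than hard-coding printed Hz values, which
cannot be simultaneously correct at 173.61 Hz and 256 Hz. At 256 Hz the
five bands land on (64,128], (32,64], (16,32], (8,16], (0,8] Hz, and the
conventional names gamma/beta/alpha/theta/delta are kept as display aliases
for D1/D2/D3/D4/A4.

Features are computed on the raw coefficients (not on reconstructed
sub-band signals), which is what makes the energy bookkeeping exact.

## Statistics

For a coefficient sequence s₁…s_N:

| statistic | formula | notes |
|---|---|---|
| variance | (1/N) Σ (sₙ − μ)² | population divisor N |
| sd | √variance | |
| kurtosis | (1/N) Σ ((sₙ − μ)/σ)⁴ | non-excess; Gaussian → 3 |
| entropy | Σ sₙ² ln sₙ² | non-normalized; 0·ln 0 = 0 |
| lbp | ln((1/N) Σ sₙ²) | logarithmic band power |

Logarithms are natural by default; base 10 is selectable. The choice only
rescales features monotonically but is fixed for reproducibility. The
entropy is implemented without a leading minus sign — the global sign flip
is irrelevant to any classifier. Degenerate inputs raise a domain error:
kurtosis of a constant sequence (σ = 0; a 0.0 sentinel is selectable for
batch robustness) and LBP of an all-zero sequence (−∞).

Multi-channel feature vectors concatenate channels (channel-major, then
sub-band in D1, D2, D3, D4, A4 order, then statistic); ordering metadata
travels with every vector and matrix, and grid runs slice columns by
statistic from it.

## Classifiers and cross-validation

- **LDA** — pooled-covariance linear discriminant. When the within-class
  scatter is singular (features constant within classes), the fit falls
  back to the nearest class centroid, which is LDA's limit as the pooled
  covariance collapses isotropically.
- **Linear SVM** — hinge loss, bounded iterations, one binary machine per
  class fused by maximum decision value (one-vs-all) for three classes.
- **KNN** — Euclidean distance, k = 5, majority vote. Ties break to the
  class owning the nearer neighbour, then to the first class in sorted
  class order; the tie-break is part of the contract and tested.
- **ANN** — one hidden layer of 5 logistic nodes, softmax output, Adam with
  learning rate 0.2 (appropriate for a net this small on standardized
  features), early stopping on a 10 % validation split of the training
  fold with patience 50, seed-controlled initialization. Early stopping on
  a small validation split is intentionally conservative: it bounds
  capacity but can halt before the training set is perfectly fit.

Features are z-scored per training fold for the distance- and margin-based
methods (KNN, SVM, ANN); LDA is scale-equivariant and is fit raw.
Standardization parameters come from the training fold only — no test-fold
statistics leak.

Cross-validation is stratified 10-fold by default (per-fold class
proportions within one sample of global). Per-fold accuracy is
100 × correct / held-out count; the overall accuracy is the exact
arithmetic mean of fold accuracies and the reported dispersion is the
sample standard deviation across folds. A pooled confusion matrix over all
held-out predictions is returned, whose trace equals the total correct
count. `group_folds=True` switches to subject-aware stratified folding so
no subject appears on both sides of a split — segment-level folding can
leak subject identity and flatter the accuracy, so both regimes are
offered. Grid runs reuse one fold partition across every
(statistic, classifier) cell for comparability.

## Synthetic data generator

The generator emulates exactly the signal properties the features measure:

- one sinusoidal oscillator per EEG band at its canonical centre (2, 6, 10,
  20, 40 Hz), random phase, ±3 % frequency jitter, amplitudes set so the
  oscillator power ratios equal the requested relative band powers and the
  total oscillator RMS equals `amplitude_uv` (default 30 µV);
- 1/f^a background noise (default a = 1, RMS 5 µV);
- optional Poisson biphasic spikes (70 ms one-cycle sine bursts at 6× the
  signal scale) as a crude epileptiform stand-in — they raise kurtosis and
  broadband detail power, which is what the classifier sees;
- optional eye blinks: 400 ms raised-cosine transients at 5× the background
  SD, mixed into every channel with random gains and emitted nearly clean
  on a synthetic EOG channel, so ICA removal is demonstrably effective.

Class presets: *neurotypical* is alpha-dominant; *epilepsy* is slow-wave
dominant with 2 Hz spikes; *autism* has elevated delta/theta and reduced
alpha — a caricature of commonly reported group-level spectral differences,
chosen so the three classes are separable by band-power statistics.

What the generator does **not** emulate: volume conduction and realistic
channel covariance, non-stationarity within a segment, seizure morphology
beyond spike trains, muscle or electrode artifacts, inter-subject
variability within a class (each segment draws fresh oscillator phases, so
segment-level and subject-level folding coincide on synthetic data).
Passing the synthetic recovery tests therefore demonstrates that the
pipeline's machinery is correct and that its features capture planted
spectral differences — not that clinical-grade accuracy transfers to real
recordings.

Synthetic experiments in the test and acceptance suites use 10 s segments
at 256 Hz with 60–100 segments per class: long enough for stable sub-band
statistics at a size that keeps the full suite fast. The generator's
default segment length remains 50 s, matching the pipeline's default
analysis window.

## File formats

Plain-text signals are one sample per line (blank lines ignored, decimal
point only). EDF reading goes through `mne`; writing (for fixtures and the
`simulate` command) uses the package's own minimal EDF writer — ASCII
header, one-second records, 16-bit quantization over each channel's
observed range — whose output `mne` reads back within the quantization
step. Mixed per-channel sampling rates in an EDF are rejected rather than
silently resampled. Feature matrices are CSV with `channel|subband|statistic`
column headers plus label/subject/segment metadata columns and a JSON
sidecar carrying the feature configuration.

## Known limitations

- The zero-phase filter is applied in the frequency domain (see above);
  users requiring strict time-domain causality should use `causal` mode.
- The EDF writer supports integer sampling rates only.
- ICA-based blink removal needs at least two non-EOG channels and one EOG
  reference; there is no template-based single-channel fallback.
- No wavelet-packet or continuous wavelet analysis; no kernel SVMs, deep
  networks, or hyperparameter search — the pipeline's hyperparameters are
  fixed by design.
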