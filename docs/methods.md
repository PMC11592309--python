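# Methods

This note records the model, the numerical choices, and the limits of what
the test suite demonstrates.

## Signal model and preprocessing

Input is a single EEG channel sampled at 100 Hz plus an epoch-level
hypnogram. The nominal 0.5–100 Hz band-pass is not realizable at a 50 Hz
Nyquist frequency, so the filter is a 0.5–49 Hz 4th-order Butterworth
applied forward–backward (zero phase); this preserves the intent — drift and
high-frequency noise removal — while being well-posed. Filtering is applied
to the continuous record before epoching. Epochs are non-overlapping 30 s
segments (3000 samples) aligned to the annotation grid; a trailing partial
epoch is dropped. R&K labels map onto the five AASM classes (3 and 4 merge
into N3); MOVEMENT/UNKNOWN epochs are removed and the survivors re-indexed.
Each night is trimmed to the span from 30 min before the first non-wake
epoch to 30 min after the last one; "sleep onset" is operationalized as the
first epoch labelled anything other than W. Non-100 Hz inputs are rejected
rather than resampled.

## Wavelet sub-bands

Each epoch is decomposed with a 4-level DWT (symmetric boundary extension).
Components are obtained by single-branch inverse reconstruction — zero every
other coefficient band and invert — so the five time-domain components sum
to the input to machine precision and all feature formulas operate on
equal-length signals (reconstructions, not coefficient vectors). Twenty
wavelet functions are supported (db/sym/coif 4 each, bior/rbio 1.1–4.4);
`db4` is the default. The property suite verifies additivity and linearity
for every listed wavelet.

## Feature definitions and guards

Moments use the population (1/N) convention throughout, so kurtosis of a
Gaussian is ≈3 (not excess). Hjorth mobility is √(var(Δx)/var(x)) and
complexity is the ratio of mobilities, with derivatives as first
differences. Frequency-domain statistics are moments of the FFT magnitude
spectrum; the "mean square" is of the magnitude spectrum by default
(config-switchable to the signal); Mpsd is the mean periodogram bin and
P the trapezoidal integral of the periodogram over frequency.

Nonlinear features and their defaults (all config-exposed):

* **Approximate entropy** — template length m = 2, tolerance
  r = 0.2·σ(x) (standard practice; the source formulation leaves both
  unset). Self-matches are included (the N−m+1 denominator convention), so
  Φ is always defined. The implementation visits template pairs through a
  sorted two-pointer sweep; it is count-for-count identical to the textbook
  O(n²) double loop, which the tests verify bit-exactly at n ≤ 100.
* **Shannon entropy** — 16 equal-width bins over the observed range,
  natural log; a constant signal has entropy 0.
* **Differential entropy** — the Gaussian closed form ½log(2πσ²) as used in
  the EEG feature literature (note it omits the additive ½ of the exact
  Gaussian differential entropy; the form is kept as-is deliberately).
  Zero variance is floored at −30 so no −∞ reaches the classifier.
* **C0 complexity** — residual energy fraction after keeping only FFT bins
  with power above the mean; ∈ [0,1]; defined as 0 for the zero signal.
* **Higuchi FD** — intervals T = 1…10, curve length averaged over the T
  decimated sub-series (the average, not the sum — the sum would shift the
  log–log slope by −1 and break the line→1, noise→2 limits), slope of
  ln L(T) vs ln(1/T). A flat signal returns 0.

Power ratios add 1e−12 to the denominator; a zero-power band therefore
yields a large finite sentinel rather than ∞. Every epoch yields exactly
105 finite values; the vector layout is 19 features × bands (d1, d2, d3,
d4, a4) followed by the 10 ratios.

## Windows, normalization, cross-validation

Classifier input windows are causal — epochs t−2, t−1, t, labelled with
epoch t — because staging and Viterbi decoding both run forward in time.
The first two windows of a night repeat the first epoch, keeping one window
per epoch so whole-night decoding stays aligned. Features are z-scored with
train-fold statistics only (scale floored at 1e−8). Cross-validation splits
at night granularity: nights are shuffled once per seed, partitioned into k
near-equal test groups (39 nights, k=10 → nine groups of 4, one of 3), and
20% of each fold's remaining nights (at least one) become the validation
set used for early stopping and HMM estimation — night-level rather than
epoch-level to avoid leakage across a night.

## Classifier

A single-layer LSTM, hidden size 20, final-step linear read-out to a 5-way
softmax, unweighted cross-entropy. The network and its
backpropagation-through-time gradients are written directly in NumPy: at
this size (105→20, T=3) dense matmuls are fast, training is exactly
reproducible bit-for-bit under a fixed seed, and the gradient code is
verified against finite differences in the tests. Training hyperparameters
(not fixed by the source method): Adam, learning rate 1e−3, batch 128, up
to 100 epochs, early stopping with patience 10 on validation accuracy,
best-validation checkpoint restored. Any object with the same
`fit`/`predict_proba` surface can be plugged in instead.

## HMM correction

λ = {A, B, π} over the fixed state order (W, N1, N2, N3, REM), with the
observed alphabet equal to the state set. A comes from bigram counts of the
*true* validation sequences, B from joint (true, predicted) counts using the
same fold's trained classifier, both with additive smoothing α = 1 so no
observation has zero likelihood; π = [1,0,0,0,0] since nights begin awake.
Decoding is per night (never concatenated across nights), in log space,
ties broken toward the lower state index. The estimator is consistent (max
entry error < 0.02 at 1e5 simulated transitions) and the decoder matches
exhaustive path enumeration.

## Synthetic data: what it emulates and what it does not

The generator produces a persistent 5-state chain (self-transition 0.85,
remaining mass spread evenly, start in W — the regime where HMM correction
is informative) and renders each epoch as one stage-specific oscillator —
frequency drawn per-epoch from a narrow band, uniform random phase — plus
white Gaussian noise (σ = 1, amplitudes 2–3). The stage bands are chosen so
each stage dominates a *different* DWT sub-band (W→d1, N2→d2, N1→d3,
REM→d4, N3→a4): a testing convention that makes class signal traceable
through the pipeline, not a physiological claim. There are no spindles,
K-complexes, artifacts, inter-subject variability, or class imbalance, so
passing benchmarks demonstrate that the pipeline's machinery is correct and
that the protocol (fold hygiene, no leakage, correction plumbing) works —
not that real-EEG accuracy figures are reproduced. Running on real
sleep-cassette EDFs uses the same code path via the `edf` input manifest.

## Benchmark problem sizes

The label-noise benchmark uses 40 nights × 1000 epochs with 15% symmetric
noise (20 nights fit λ, 20 are decoded). The end-to-end benchmark uses 20
nights × 1000 epochs — the same night length, comparable to a real ~9 h
recording — through the full pipeline with 10 folds. Night length matters
for the corrector: with ~4 validation nights the α = 1 smoothing leaves
B's diagonal log-odds at ln(c+1) for c counts per state, and short nights
(c ≈ 100) make the transition prior overpower correct observations,
flattening genuine single-epoch stage visits. At 1000-epoch nights
(c ≈ 800) the observation term dominates for all but the most
underrepresented transitions.

## Known limitations

* With a near-error-free classifier, MAP (Viterbi) decoding under smoothed
  count estimates is not exactly the identity: it can still flatten a few
  true single-epoch stage visits whose transitions happen to be rare in the
  validation counts. On the end-to-end benchmark this costs ≲0.05% accuracy
  against a perfect raw prediction; in the intended operating regime
  (classifier error ≳ a few percent) correction is strictly beneficial, as
  the noisy-chain benchmark shows (+7.5 points at 15% noise).
* N1-like sparse classes are not modelled by the symmetric synthetic chain;
  real class imbalance behaviour is untested here.
* The EDF writer covers the single-channel 16-bit case used for synthetic
  export; arbitrary multi-signal EDF writing is out of scope.
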