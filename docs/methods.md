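# Methods

This note documents the models and procedures the package implements, the
defaults it chooses where the method family leaves a decision open, and what
the synthetic benchmark can and cannot show.

## Synthetic data model

A dataset mimics the geometry of the common multimodal affective benchmark:
`n_subjects x n_trials` trials, each a 40 x 8064 array (32 EEG channels in
the standard 32-electrode montage order, then 8 peripheral channels) at
128 Hz — 63 s covering a 3 s baseline plus 60 s of stimulus. Each trial
carries four continuous ratings (valence, arousal, dominance, liking) drawn
uniformly on (1, 9); classification tasks binarize a rating at the scale
midpoint 4.5, with the boundary value mapped to "low" (strictly greater
than 4.5 is "high").

EEG channels are a sum of four band-limited oscillations — theta (3–7 Hz),
alpha (8–13 Hz), beta (14–29 Hz), gamma (30–47 Hz) — plus AR(1) noise
(coefficient 0.6, unit innovation variance). Each oscillation is three tones
with frequencies and phases drawn once per channel and band and then *fixed
across all trials of the dataset*. This stimulus-locked construction is
deliberate: the emotion effect scales band amplitudes (alpha multiplied by
`1 − 0.4·effect_size·a`, beta by `1 + 0.4·effect_size·v`, where `a` and `v`
are the latent arousal/valence scores mapped to (−1, 1)), and fixing the
tone phases makes that amplitude modulation visible both to spectral
estimators and to learners operating on the raw waveform. Had the phases
been redrawn per trial, the modulation would be invisible to any linear
function of the waveform and only quadratic (energy) features could recover
it. Baseline band amplitudes are 0.7 / 1.0 / 0.8 / 0.5
(theta/alpha/beta/gamma), chosen so `effect_size = 1` yields moderate
separability against the noise floor and `effect_size = 2` a strong effect.
A per-subject multiplicative gain, lognormal with sigma 0.2, emulates
inter-subject amplitude variability and creates the usual cross-subject vs
single-subject performance gap. Peripheral channels are a slow sinusoidal
drift (0.05–0.4 Hz) plus white noise whose standard deviation is weakly
modulated by the latent scores.

What the generator does **not** emulate: ocular/muscular artifacts, channel
cross-talk and volume conduction, non-stationary band structure within a
trial, realistic 1/f spectral slopes, or phase randomness across trials.
Passing tests therefore demonstrate that each pipeline stage recovers the
structure it targets from clean band-power signals — not that the pipeline
reaches any particular accuracy on real recordings.

Determinism: a dataset is a pure function of `(n_subjects, n_trials, seed,
effect_size)`, bit-for-bit. The on-disk container is HDF5 (`/signals/s{SS}`
one array per subject, `/ratings` a table mirrored to a CSV side-car); an
adapter reads/writes the per-subject pickled dialect (`data`:
trials x 40 x 8064, `labels`: trials x 4) used by the preprocessed benchmark
distribution, exercised here only on files the package itself writes.

## Trimming and augmentation

Downstream stages use the final 3840 samples of each trial (the last 30 s of
the stimulus; the baseline and first half are dropped). Channel-level
augmentation treats every channel of every trimmed trial as one instance
inheriting the trial's labels: 32 EEG / 8 peripheral / 40 fused instances
per trial (40,960 / 10,240 / 51,200 at full scale). Each instance is
z-scored over its 3840 samples; this removes absolute amplitude, so learners
on augmented data must rely on relative (spectral-shape) information. Splits
of augmented data are grouped by trial by default so that no trial
contributes instances to both sides; an ungrouped mode replicates the
historical protocol in which pieces are split freely.

## Feature bank

Per EEG channel (54 features): power, mean, standard deviation (T−1
denominator), normalized first/second absolute differences; Hjorth mobility
and complexity (forward-difference derivative, biased variance; activity is
the variance itself and is not duplicated in the bank); the non-stationary
index (variance of the 32 segment means of the z-scored signal); the Higuchi
fractal dimension (kmax = 8, least-squares slope of ln<L(k)> vs ln k,
clipped to [1, 2]); ten higher-order crossings (strict sign changes of the
repeatedly backward-differenced, demeaned signal, exact zeros removed); the
power-law exponent (least squares on the log-log Welch PSD over 3–47 Hz);
fourteen short-time band-power statistics (128-sample Hamming frames, no
overlap, per band the natural log of the mean/max/min frame band energy,
plus the across-band power variance and the beta/alpha ratio); four
bispectral summaries; twelve db4 wavelet features (entropy, RMS, |ln REE|
per band); and four Hilbert–Huang band energies. Per peripheral channel
(31): the same minus the fractal dimension, band-power and bispectral
blocks, with wavelet entropy and |ln REE| only. Pairwise blocks over the 14
lateral symmetric electrode pairs add 56 coherence, 56 differential- and 56
rational-asymmetry columns. Totals: 1896 EEG + 248 peripheral = 2144 fused.

Estimator settings:

* **Welch PSD / coherence** — 853-point Hamming window, 426-sample overlap,
  density scaling (7 averaged segments on a 3840-sample window).
* **Band power** — the band value of a frame is the summed squared spectral
  magnitude over the band's bins (band energy). The sum rather than the
  per-bin mean keeps equal-energy tones in different-width bands comparable,
  which the beta/alpha ratio requires.
* **Bispectrum** — indirect (cumulant) estimate: 30 non-overlapping
  128-sample demeaned slices, third-order cumulants to lag ±63 averaged over
  slices, optional Rao–Gabr lag taper (uniform by default), 2-D 128-point
  FFT with quadrant shifting. The principal region is the triangle
  0 ≤ f2 ≤ f1, f1 + f2 ≤ fs/2. BE1/BE2 are entropies (natural log) of the
  normalized magnitude and squared-magnitude distributions over the
  triangle; MMOB is the mean magnitude there; FOSM sums log-magnitudes over
  the whole matrix, skipping exact zeros where the logarithm is undefined.
* **Wavelets** — 4-level db4 with zero-padding (so a plain convolution
  cascade reproduces the coefficients exactly); sub-band-to-rhythm mapping
  D4=theta, D3=alpha, D2=beta, D1=gamma per the dyadic frequency ranges at
  128 Hz (D1's 32–64 Hz intentionally overshoots the 47 Hz gamma edge —
  the mapping follows the dyadic table rather than the band definition).
* **Empirical mode decomposition** — the sifting procedure uses a
  segment-wise extrema detector (one maximum and one minimum per 128-sample
  block) with mirror-extended cubic-spline envelopes; the stopping rule per
  sift is sum((h_prev − h)²)/sum(h_prev²) < 0.25, and extraction stops when
  the mean absolute residue falls below 1e−3, the residue loses its
  extrema, or 10 IMFs are reached. A scalar mean-residue criterion would
  halt immediately on any zero-mean signal, hence the absolute value. The
  block-wise detector cannot resolve envelope variation faster than one
  extremum per second, so a standard all-local-extrema mode is available
  (`extrema_mode="local"`) and is what separates, e.g., a 5 Hz from a 40 Hz
  tone into distinct IMFs. Completeness (sum of IMFs + residue = input)
  holds exactly by construction.
* **Hilbert–Huang spectrum** — instantaneous energy is |z(t)|² of the
  analytic signal; instantaneous frequency is the unwrapped phase
  difference times fs/(2π) (the dimensionally consistent reading), clipped
  to [0, fs/2]; band energies sum the energy of samples whose instantaneous
  frequency falls in the band, normalized by the window length.

Failed per-feature computations become missing values and are imputed with
the column median.

## Feature selection

The variance filter removes features with sample variance strictly below
0.01 (a variance of exactly 0.01 survives). The chi-square scorer min-max
scales each feature to [0, 1] first (non-negativity); the mutual-information
scorer discretizes each feature into 10 quantile bins and evaluates the
plug-in estimate in nats — a deterministic, seed-free choice; the Fisher
score is the between-class mean separation over the within-class variance,
with zero within-class variance and separated means scored as infinite.
The final filter takes the union of the chi-square and mutual-information
top-200 lists. The greedy forward wrapper then adds, at each step, the
feature that maximizes mean stratified k-fold CV accuracy (folds fixed and
seeded before the loop, ties to the lowest index) and stops when no
candidate improves the best accuracy by more than 1e−6; single features
that alone reach perfect accuracy can be skipped as an overfitting guard
for tiny datasets.

## Deep models

All networks are implemented in numpy with hand-written gradients and an
Adam-style optimizer (the only gradient-descent variant used).

**Denoising autoencoder.** Encoder h = sigmoid(W x̃ + b), linear decoder
z = W′h + b′ with untied weights; the corrupted x̃ zeroes exactly
round(q·d) uniformly chosen coordinates (q = 0.2 by default) — the fixed
count makes corruption statistics deterministic. Training minimizes the
mean squared error between z and the *clean* input. The encoder consumes
the corrupted input; a literal reading that encodes the clean input would
make the denoising criterion vacuous.

**Stack.** Default architecture 3840-1000-200-40 with a 2-way softmax head
fed only by the top code. Greedy pre-training trains each layer on the
clean codes of the layer below, applying its own corruption. Supervised
fine-tuning minimizes l0·CE + l1·L1 + l2·L2 + l3·C (defaults 1, 1e−4,
1e−4, 0.5) where C is the class-imbalance misclassification cost with
inverse-class-frequency weights; the reported C uses hard error counts (so
it is exactly zero when every prediction is correct) while its gradient
uses the smooth expected-cost surrogate. With a validation set,
`restore_best` selects the best-validation epoch — epoch selection on a
validation set is part of the evaluation protocol. An unrolled
encoder–decoder fine-tuning mode (`sda_autoencoder_finetune`) minimizes
end-to-end reconstruction error and records the per-epoch trace, whose
epoch-0 entry measures the quality of the initialization (pre-trained vs
random).

Optimization defaults: the pre-training recipe uses mini-batches of 32 at
learning rate 3e−3. At the short epoch budgets used throughout the package
(20 epochs per layer), larger batches leave the wide first layer visibly
underfit — with batch 128 at 1e−3 the held-out reconstruction MSE on
unit-variance data stalls near 0.97, versus 0.67 with the default recipe
at identical epoch counts — so the defaults spend more, smaller steps
rather than more epochs.

**RBM / DBN.** A restricted Boltzmann machine layer with binary hidden
units and binary or Gaussian visible units (Gaussian for real-valued
inputs), trained by single-step contrastive divergence; the energy of the
binary model is −vᵀWh − bᵀh − cᵀv. Stacking RBMs and adding a logistic
output yields the deep-belief reference.

**Baselines.** The DNN is 3840-800-200-20-2 with batch normalization, ReLU
and dropout 0.45/0.5/0.25 after each hidden affine layer. The CNN reshapes
each instance to a 60 x 64 image and applies four convolution modules
(kernel 3, stride 2, no padding; batch norm + ReLU each; 2 x 2 max-pooling
after the last two, skipped when a spatial dimension has collapsed to 1),
channel widths 1-8-16-32-32, then a fully connected softmax head with 0.85
dropout. Channel widths are this package's choice; the reference
architecture specifies only the kernel/stride/padding/pooling layout.

## Evaluation and fusion

Cross-subject evaluation mixes all trials and runs stratified seeded 5-fold
CV (a fixed stratified 60/20/20 split — 768/256/256 at full scale — is
available for the deep models). Single-subject evaluation is leave-one-out
over one subject's trials, accuracy = correct/n, skipped with a warning
when a class has fewer than two trials. Decision fusion averages the two
modalities' class-probability vectors with weight w on EEG; the weight is
found by exhaustive search over {0, 0.01, …, 1} (101 candidates, ties to
the smallest w) on validation predictions. The optimal-weight accuracy is
guaranteed to be at least the equal-weight accuracy only on the data the
search saw.

## Problem sizes and reproducibility

The test suite and the acceptance script run the deep pipeline on a reduced
study condition — 4 subjects x 10 trials (1280 EEG instances), 20
pre-training epochs per layer and 20 fine-tuning epochs — and the feature
bank on a handful of trials; these sizes are the package's standing
benchmark configuration. Every stochastic step (generation, fold
assignment, corruption, weight initialization, batch order) is driven by an
explicit seed, and the full generate → train → encode → classify chain is
bit-reproducible on one machine.

## Known limitations

* The segment-wise extrema detector makes the default EMD insensitive to
  envelope variation faster than the block rate; use the local mode when
  mode separation matters.
* On per-instance z-scored waveforms the class signal is a *relative*
  band-power shift; recovering it requires (approximately) scale-invariant
  energy features. A linear probe on log alpha-band powers recovers the
  arousal split almost perfectly on the strong-effect condition (the
  `alpha_power_linear_accuracy` quantity of the acceptance script), while
  the sigmoid autoencoder stack reaches a markedly lower held-out accuracy
  (`sda_svm_heldout_accuracy`) that does not improve with substantially
  longer fine-tuning — the information is present but the stack's sigmoid
  codes are a weak substrate for log-energy ratios at this sample size.
* A deeper stack whose extra layer shrinks the code (40 vs 200 units)
  reconstructs *worse* than its shallower counterpart — the bottleneck
  carries less information — so depth only pays when paired with adequate
  code width and training time.
* The misclassification-cost term is piecewise constant in the parameters;
  it shapes model selection and reporting, and its training influence comes
  through the smooth surrogate.
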