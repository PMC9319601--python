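# Methods

This note documents the models, parameter choices and numerical
decisions behind `eegemo`, and what the synthetic experiments do and do
not establish about real EEG.

## Synthetic EEG generator

Each recording is a `(n_channels, 1000)` window at 200 Hz (the sampling
rate is a free parameter; the 200 Hz default makes a 1000-sample window
span 5 s and resolves all bands up to β = 30 Hz).  Informative
channels carry, per canonical band (δ 1–4, θ 4–8, α 8–13, β 13–30 Hz),
three sinusoids with frequencies drawn uniformly inside the band and
uniform phases; amplitudes are `base_amplitude × class_band_gain ×
subject_factor`.  Non-informative channels, and every channel
additively, receive white Gaussian noise (`noise_sd = 1`).  Default
class gains differ only in β: negative 0.5×, neutral 1×, positive 2×
(a `with_beta_contrast(g)` helper sets g / 1 / 1/g).  The optional
per-subject lognormal amplitude factor (σ = 0.1) makes cross-validation
splits non-trivial.

Randomness is keyed by hashing `(seed, subject, trial, label)` into an
independent stream per recording, so datasets are reproducible and
individual recordings do not depend on generation order.

What the generator does *not* model: 1/f background spectra, eye-blink
and EMG artifacts, volume conduction and inter-channel correlation,
non-stationarity within a window, or the stimulus structure of real
film-clip experiments.  Passing tests therefore demonstrate that the
pipeline recovers controllable band-power class structure — not that it
reaches any particular accuracy on real recordings.

## Wavelet analysis and synthesis

The CWT is computed literally as the Riemann sum
`W(m, n) = m^{-r} ∑_t u[t] ψ*((t − n)/m)` with `r = 1/2` (L2, default)
or `r = 1` (L1), evaluated by FFT correlation with time-sampled daughter
wavelets.  A brute-force double loop over `(scale, shift)` serves as the
independent oracle in the tests; the two agree to round-off.

Wavelet families: generalized Morse `ψ̂(ω) = a ω^β e^{−ω^γ}` (γ=3,
β=20; peak-normalized, exactly analytic and zero-mean; its time-domain
form is obtained once per parameter set by an inverse-FFT quadrature
accurate to ~5e-12 and cached as a cubic spline) and the analytic
Morlet with the zero-mean correction term (ω₀=6, closed form in both
domains).  A non-admissible Gaussian bump exists so the admissibility
guard has a true negative.  Daughters are truncated where |ψ| falls
below ~1e-12 of peak (radius 9 scale units for Morlet, ~30 for Morse).

Scales: 64 logarithmic scales covering equivalent frequencies 1–45 Hz
via `f = ω_peak · fs / (2π m)`.  Boundaries: the signal is mirror-padded
by one maximum wavelet support (capped at the signal length) and
trimmed, suppressing edge artifacts in rendered images; a `zero`
boundary treats the signal as zero outside its domain and matches the
defining integral exactly.

The inverse transform discretizes the double-integral synthesis formula
over the log-scale grid: `u ≈ (2/C_ψ) Re ∑_j Δ(ln m_j) (W_{L1,j} *
ψ_{m_j,L1})`, with `C_ψ = ∫₀^∞ |ψ̂|²/ω dω` by adaptive quadrature.
Coefficient rows are extended past the edges by conjugated reflection
(consistent with the mirrored forward transform, since a real-spectrum
wavelet satisfies ψ(−t) = ψ*(t)); without this the edge error triples.
On band-limited signals (5–25 Hz, 1000 samples) the relative L2
reconstruction error is 0.4–4%; the 45 Hz upper scale limit makes the
resolution of identity fall off above ~30 Hz, so signals with
substantial energy there reconstruct worse.

Scalogram images: log1p magnitude, per-image min–max normalization,
bilinear resize to 224×224 (values first, colormap lookup after — no
color-space mixing), jet colormap by default.  Per-image normalization
matches how such images are fed to pretrained backbones, but it couples
all pixels through the image maximum; the consequences for channel
scoring are discussed below.

## Feature extraction

The extractor contract (`name`, `output_dim`, `extract`) keeps CNN
backbones optional plug-ins.  The bundled grid-stats extractor computes,
over 1×1/2×2/4×4/8×8 grids (85 cells), per-cell intensity mean and
variance and a magnitude-weighted 8-bin gradient-orientation histogram:
850 features zero-padded to q = 1000, the conventional backbone output
width.  Mean features respond to brightness; orientation features are
insensitive to constant brightness shifts up to round-off in bin
assignment.  Convolution layer arithmetic uses
`Y_out = (Y_in + 2p − k)/s + 1` with exact-divisibility enforcement, and
the softmax cross-entropy uses the natural logarithm, the standard
convention.

## Differential-entropy channel selection

For discrete attributes, `E(P | U ⊕ C) = −(1/|U|) ∑_x log₂(|[x]_C ∩
[x]_P| / |[x]_P|)`, which simplifies to `−(1/|U|) ∑_x log₂(|[x]_C| /
|[x]_P|)` because `[x]_C ⊆ [x]_P` for `P ⊆ C`.  It is 0 iff `U/P = U/C`,
bounded by `log₂|U|`, and non-decreasing under partition coarsening —
all property-tested, with a brute-force intersection-form oracle.

Channel scoring faced two genuinely open design questions:

*Orientation.*  Two readings of the score are possible: keep subsets
with low E (they mimic the full set's partition) or with high E (they
carry concentrated shared information).  We rank
**descending**: with many-dimensional continuous features the full
condition set C shatters the universe, so E(P) reduces to the mean log
block size of P's partition — high for channels whose features are
mutually redundant because a common (class-driven band-power) factor
drives them, and ≈ 0 for channels of independent noise, which shatter U
on their own.  High entropy = high shared information; the ascending
convention would select noise first.

*Granularity.*  Scoring a channel's full feature block jointly
degenerates (every block shatters U).  Instead each channel is scored by
the **mean subset entropy over feature pairs** among its 20 most
representative columns (highest mean absolute correlation with the rest
of the channel's block; label-free), discretized by equal-frequency
binning into 4 bins.  Pairs are the smallest subsets that expose
redundancy, and averaging ~190 of them gives a low-variance statistic.
The defaults (4 bins, 20 columns) come from a robustness study on the
generator's stated conditions: 20/20 seeds recover all informative
channels at β contrast 2× and 3×, with a clear score gap.  Equal-
frequency binning with 10 bins remains the default for general decision
tables (`discretize_features`), where no pairing is involved.

A caveat: per-image min–max normalization gives *noise* channels a weak
common factor (the image maximum), inflating their redundancy slightly;
the class-driven factor in informative channels dominates it under the
study conditions, but the margin shrinks as class contrast drops.

Ties break by ascending channel index.  The decision attribute (label)
is carried in the table for stratification but never enters the entropy.

## BoDF encoding and classification

Per-class k-means (k-means++, 10 restarts, fixed seed) builds one
codebook per emotion class, concatenated in class order; `k = 8` by
default, the grid {8, 10, 12, 14} selectable per training fold by
cross-validated accuracy (a silhouette evaluator is provided for latent
cluster-count questions).  Each recording's selected per-channel vectors
are counted into their Euclidean-nearest codeword (ties to the lowest
index), so counts always sum to the number of encoded vectors.  Feature
vectors are standardized (per-column z-score, fitted on the training
fold) before clustering and encoding: raw grid-stat columns differ in
scale by orders of magnitude and would otherwise dominate the Euclidean
geometry.

Classifier heads map the field's GUI-style names to concrete estimators:
cubic SVM → polynomial kernel degree 3 (scaled inputs); fine KNN → 1-NN;
medium tree → decision tree capped at depth 20; subspace KNN → 30-learner
random-subspace bagging of 1-NN on half the features.  Evaluation is
stratified 5-fold cross-validation at the recording level (optionally
grouped by subject); every data-dependent fit — discretization, channel
ranking, standardization, vocabulary — is restricted to the training
fold, and the report records which recordings fed each fold's k-means so
the hygiene is auditable.  Reports are byte-identical across reruns with
the same seed.

## Problem sizes

The bundled experiments use 8-channel montages with 4 informative
channels: 45 recordings × 20 seeds for channel recovery and 90
recordings (5 subjects × 6 trials × 3 classes, β contrast 3×) for the
end-to-end evaluation — sizes at which every claim in the test suite is
reproducible on a single CPU in minutes while keeping the per-class
recording count (30) comparable to a real session.  Oracle equivalence
uses 64–128-sample signals where the brute-force double loop is exact
and cheap.

## Known limitations

- The synthetic generator's simplicity means channel selection is tested
  against independent-noise alternatives, not against correlated
  artifact sources (volume conduction would make "redundant" channels
  that carry no emotion information).
- The entropy statistic is label-free; it finds *structured* channels,
  which coincide with informative ones only when class structure is the
  dominant shared factor.
- Scalogram rendering normalizes per image, discarding absolute power;
  classification relies on within-image patterns plus the encoding's
  count geometry.
- The inverse CWT targets band-limited signals inside the analyzed
  1–45 Hz range; broadband or near-Nyquist content reconstructs with
  larger error.
- The depth-capped tree head is consistently the weakest on BoDF
  histograms (small sample, axis-aligned splits); this mirrors its role
  as a comparison baseline rather than a recommended classifier.
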