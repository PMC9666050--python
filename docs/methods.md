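# Methods

This note documents the models, conventions and design choices behind
`semgkit`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic benchmarks do and do not show.

## Wavelet packet filter bank

A level-`L` wavelet packet transform recursively applies an orthonormal
low-pass/high-pass pair to *every* node of the decomposition tree,
filtering and downsampling by two, producing `2^L` terminal coefficient
sequences. Conventions:

* **Filters.** Only the low-pass (scaling) table `h` is stored per basis
  (`src/semgkit/_filter_tables.py`, with provenance notes); the high-pass
  filter is derived as `g[k] = (−1)^k h[L−1−k]`. Two tables required
  repair before they could honour the orthonormal contract:
  * *dmey*: the standard 62-tap FIR approximation of the Meyer wavelet is
    only approximately orthogonal (`Σh² − 1 ≈ 2.2e−3`), which produces
    ~1e−2 reconstruction errors in any implementation that treats it as
    orthogonal. We project the published table onto the exact orthonormal
    quadrature-mirror manifold (largest coefficient change 7.7e−4), after
    which perfect reconstruction and Parseval hold to machine precision
    while the filter remains a discrete-Meyer approximation of the same
    quality.
  * *fk8*: the length-8 Fejér–Korovkin filter is embedded from its
    published table (available here to ~1e−6) and refined the same way
    (largest change 2.6e−6).
* **Boundaries.** Periodization is the default: the signal is zero-padded
  at the tail to a multiple of `2^L`, treated as circular, and truncated
  back after reconstruction. This makes the transform an orthogonal
  matrix, so energy conservation and invertibility are exact — which in
  turn makes the feature definitions crisp (sub-band RMS² sums to window
  energy). Half-point symmetric extension is available for analysis-only
  use.
* **Alignment.** One analysis stage computes
  `a[i] = Σ_j h[j] x[(2i + 1 − L/2 + j) mod N]`; this phase matches the
  decimated circular convolution of standard wavelet toolboxes, and the
  test suite verifies terminal coefficients against PyWavelets to 1e−8
  for db4/sym3/coif2.
* **Ordering.** Terminal sub-bands are returned in frequency (sequency)
  order via the Gray-code-style permutation that accounts for the spectral
  mirroring of every decimated high-pass branch, so band `b` of a level-3
  transform covers `[b, b+1] · rate/16` exactly.
* **Leaf selectivity.** The leaf filters of short bases are far from
  brick-wall: a sinusoid at a band centre retains only ~64–72 % of its
  energy in its own band for sym3/db4/coif2/fk8 (the plurality is always
  correct), versus ≥ 93 % for dmey. This is an inherent property of short
  wavelet packet filters, and is why the long dmey basis is the pipeline
  default and the basis used for spectral sanity checks.

## Features

MAV and RMS are computed on the sub-band coefficients directly. MNF and
MDF use a one-sided, unwindowed periodogram of the coefficient sequence —
the simplest fully deterministic estimator, exact for on-bin sinusoids —
on a frequency axis of `rate / 2^L` (the decimated sequence's effective
sampling rate), so sub-band spectral features live on `[0, rate/2^{L+1}]`.
MDF is reported as a bin frequency with a smallest-index tie rule; no
interpolation is invented. Zero-power sub-bands yield MNF = MDF = 0 with
a warning rather than an error, since narrowband signals legitimately
produce empty bands. An optional mode computes MNF/MDF on the
band-limited reconstruction at the full rate instead.

The 64 columns are frozen in channel-major, band-minor, feature-last
order (`ch1_band0_MAV` … `ch2_band7_MDF`); PCA models and classifiers
depend on this order.

## PCA

Plain covariance PCA per the decentralised-data formulation:
`C = (1/n) XᵀX` on mean-centred columns (note `1/n`, not `1/(n−1)`),
eigendecomposition, top-k eigenvectors by descending eigenvalue, each
sign-fixed so its largest-magnitude loading is positive. Standardisation
(unit-variance columns) is available but off by default. Inside
cross-validation the PCA is fitted on the training fold only; test rows
are projected with training statistics.

## Classifiers

* **KNN** (default K = 5): Euclidean distances, majority vote; vote ties
  break by the smallest summed distance of each tied class's neighbours,
  then by the lowest class index — fully deterministic and verified
  against an exhaustive oracle.
* **SVM**: RBF kernel, C = 1, `gamma = 1/(n_features · var)`, one-vs-one
  multiclass voting (scikit-learn `SVC`).
* **Bagging**: 100 unpruned decision trees on bootstrap resamples,
  seeded (scikit-learn `BaggingClassifier`).

When `classify.train` receives raw features it z-scores columns for the
distance-based classifiers (MAV/RMS in signal units and MNF/MDF in Hz are
incommensurate). Inside the evaluation pipeline, however, the classifier
input is PCA scores, which already share one unit system; re-scaling them
would inflate noise-only components to the same weight as the informative
leading components and measurably degrades KNN (≈ 0.72 vs ≈ 0.92 accuracy
on the separation-2 synthetic benchmark). The pipeline therefore disables
the classifier-side scaler by default; callers can override via
`PipelineConfig(params={"scale": True})`.

## Evaluation protocol

Stratified k-fold (default 5) cross-validation **grouped by source
recording**: all windows cut from one trial share a fold, because
neighbouring windows of a trial are strongly correlated and splitting
them across folds would leak test information into training. With the
separability dial at 0 the classes are generatively identical, so any
such leakage would push accuracy above chance — the chance-level test
doubles as the leakage test. Subjects are evaluated separately by default
(subject-specific models, pooled confusions), with a pooled mode
available. Reported overall accuracy is `trace/total` of the pooled
confusion; per-fold accuracies (mean ± sd) are also kept. Per-class
metrics are one-vs-rest accuracy, recall, precision and F1 from the
pooled confusion.

The noise sweep trains on clean windows and adds zero-mean Gaussian noise
with standard deviation `level × reference_magnitude` to **test windows
only**, re-extracting their features; `reference_magnitude = 1` makes the
levels absolute signal units, directly comparable with the 1e−2 amplitude
scale of the emulated recordings (a 1e−2 noise level therefore already
means SNR ≈ 1 on synthetic data, and accuracy falls to chance once the
noise dwarfs the signal). The window sweep re-segments and re-extracts
per size. The Kruskal–Wallis screen uses midrank ties, tie correction and
the χ²(k−1) approximation via `scipy.stats.kruskal`; constant columns
return H = 0, p = 1 with a warning. On synthetic data only the leading
principal components are class-informative, so significance fractions
well below 1 among 30 retained components are expected.

## Synthetic generator

Each trial is amplitude-modulated coloured Gaussian noise: white noise is
shaped in the DFT domain by a per-class power profile over the eight
level-3 bands, normalised to unit variance, scaled by a per-class channel
gain pair and the 1e−2 amplitude (with ±10 % per-trial plateau jitter),
multiplied by a trapezoidal envelope (0.5 s ramps over 6 s), and topped
with a 5e−4 white sensor-noise floor. Class structure rides on three
cues, all scaled by the `separation` dial `δ`:

* band-weight patterns, `w_c = base · (1 + 0.3 δ p_c)` with sign patterns
  chosen so adjacent bands never carry opposite signs;
* an energy-neutral within-band spectral tilt (`± 0.8 δ`, clipped), which
  moves each band's spectral centroid — the main cue visible to the
  MNF/MDF features;
* channel gain patterns `1 ± 0.25 δ`.

At `δ = 0` all classes are generatively identical; at `δ = 1` they are
separable but overlapping (≈ 0.6 cross-validated accuracy); at `δ = 2`
the default pipeline reaches ≥ 0.9.

Band edges in the power profile are smoothed with a Laplacian kernel of
1/3 band width. The analysing wavelet filters have finite transition
bands with roughly exponential tails; against a brick-wall profile they
systematically pump energy from a strong band into a weak neighbour,
while a matched smooth transition makes the exchange nearly symmetric.
This, together with the adjacent-band ratio cap above, is what lets the
closed-form band-energy oracle (`expected_band_energy`: profile integral
per band × envelope mean-square × mean squared channel gain × jitter
second moment, plus the noise-floor share) agree with measured sub-band
energies to within 10 % — the residual is the sub-Hz offset of each leaf
filter's crossover frequency, which no profile shaping can remove. An
explicit `band_weights` override bypasses tilt and smoothing for exact
brick-wall control in analytic tests.

What the generator does **not** model: motor-unit action potentials and
recruitment, nonstationarity within the plateau, electrode-skin impedance
drift, power-line interference, inter-subject anatomy. Passing the
synthetic benchmarks therefore demonstrates that the pipeline recovers
class structure expressed as band energies, spectral tilts and channel
ratios at realistic amplitudes and noise floors — not that a given
accuracy will transfer to any particular real recording.

## Problem sizes and determinism

Tests and the acceptance script run on scaled-down trial sets (typically
one subject, 8–10 trials per class — 48–60 trials, 336–420 windows);
these sizes give per-accuracy standard errors of ~0.05 at the trial
level, which the chance-level and trend assertions use as their
tolerance. The generator's defaults remain at the full emulated geometry
(5 subjects × 6 classes × 30 trials). All randomness flows from explicit
seeds: the generator from `SyntheticSpec.seed`, cross-validation fold
assignment and classifier seeds from the `seed` argument via one
`numpy` Generator, so every reported number is bit-reproducible.

## Known limitations

* The symmetric boundary mode is analysis-only (no reconstruction).
* `dmey`/`fk8` are exact orthonormal refinements of published tables, so
  their coefficients differ from other toolboxes at ~7e−4 / ~3e−6
  respectively; cross-library coefficient comparisons should use
  db4/sym3/coif2.
* PCA dimension k is silently capped at `min(n_train − 1, n_features)`
  inside cross-validation on very small folds.
* Accuracies on the synthetic benchmark are not comparable to accuracies
  published for real recordings; only trends (basis ranking, noise and
  window-length monotonicity) are expected to carry over.
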