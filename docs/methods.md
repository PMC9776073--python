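# Methods

## Signal model and preprocessing

Input is a set of trials, each a channels × samples array at sampling
rate f_s with ordinal arousal/valence ratings in [1, 9]. Ratings are
binarized at the scale midpoint: > 5 is "high", ≤ 5 is "low"; the
four-quadrant task combines both axes (LALV = 0, HALV = 1, LAHV = 2,
HAHV = 3). Trials are cut into ⌊(D − T_w)/T_o⌋ + 1 windows (defaults
T_w = 3 s, T_o = 1.5 s; window sample counts are rounded half-up so the
layout is deterministic across platforms). Optional stages for raw
recordings — polyphase downsampling, zero-phase 4–45 Hz bandpass,
removal of a leading 3 s baseline — run before segmentation; baseline
removal is ordered first, which is the natural choice when the baseline
is pre-stimulus rest.

Each window is split into θ (4–8), α (8–12), β (12–30) and γ (30–45 Hz)
bands. The default decomposition computes an STFT with a 1 s Hann window
and 50 % hop, zeroes the bins outside the band, and inverts; band edges
assign a bin to the band containing it, lower edge inclusive, with γ
keeping its upper edge so the four bands exactly tile 4–45 Hz. A
zero-phase 4th-order Butterworth bandpass is available as an alternative
(`decompose_method="butter"`). The γ band requires f_s ≥ 90 Hz; lower
rates are rejected by name. The band signals of broadband noise sum to
the 4–45 Hz bandpassed input within a relative L2 error of 0.15 (checked
in the tests away from window edges, where tapering differs between the
two filters).

## Node features

Band-limited window amplitudes are modelled as Gaussian, for which
differential entropy is h = ½ ln(2πe σ²) nats. The estimator plugs in
the unbiased (n−1) sample variance; at the default window length
(384 samples at 128 Hz) the estimator's standard error is ≈ 0.036 nats.
Natural logarithms are used throughout (the closed form pairs log base e
with the factor e). A constant window has no finite differential
entropy; the estimator raises by default, or returns −inf behind a flag.

## Granger-causality adjacency

For channels x, y, the restricted model predicts the target from its own
L lags; the full model adds the source's L lags. Both are fitted by OLS
on the identical sample range t = L…n−1 after demeaning, and

    F_{x→y} = ln(RSS_restricted / RSS_full) ≥ 0,

non-negative because the models are nested. The matrix orientation is
A[i, j] = F_{j→i} (row = target, column = source), so row sums aggregate
incoming influence, matching the row-sum degree convention of the
Laplacian downstream. The diagonal is fixed at 1. The all-pairs routine
shares one precomputed lag gram matrix across the N(N−1) fits and is
tested to agree with the pairwise path to 1e-8; the pairwise path itself
is tested against an independent explicit normal-equation solve.

The lag order defaults to L = 5 (≈ 40 ms of history at 128 Hz); a
BIC-based per-pair selection over 1…max_lag is available. Exactly
collinear pairs raise a singular-design error; constant channels are
rejected by index. Raw log-ratios are reported without renormalization:
binarization is rank-based, so any strictly increasing transform of the
off-diagonal values yields the identical mask.

Binarization keeps the largest ⌊N²k⌋ entries (clamped to at least N).
Diagonal entries participate in the count and, having value 1, always
survive; off-diagonal ties break in row-major order. Masks are nested
across k, and a sweep utility evaluates a k grid (the model-selection
grid 10–90 % used in practice). GC is computed per window per band so
the adjacency matches each window's node features; a per-trial mode
computes one adjacency per trial instead (cheaper, smoother, at the cost
of ignoring within-trial dynamics).

Baseline adjacencies for comparison experiments: a symmetric seeded
Bernoulli(k) mask; a Gaussian kernel of inter-electrode distance (σ
defaults to the root-mean-square pairwise distance); and the
phase-locking value |⟨exp i(φ_i−φ_j)⟩_t| from analytic-signal phases.
A permutation-null utility (shuffling the source series, refitting only
the full model) provides significance calibration for tests; significance
masks are deliberately not the primary adjacency.

## Graph convolution

L = D − A with D = diag(row sums); L̃ = 2L/λ_max − I. For directed
adjacencies the spectral derivation's symmetry assumption fails, but the
Chebyshev recursion T_0 = I, T_1 = L̃, T_k = 2L̃T_{k−1} − T_{k−2} needs
no eigendecomposition and is applied to the asymmetric L̃ directly,
preserving edge direction; λ_max is taken from the symmetrized Laplacian
(L + Lᵀ)/2 and floored at 1e-6 so empty graphs rescale to −I without
dividing by zero. An optional symmetrization of A ((A+Aᵀ)/2, or its
any-nonzero→1 variant) supports ablation. On symmetric graphs the
recursion agrees with the dense spectral filter U g_θ(Λ) Uᵀ X W to 1e-8
(tested over random graphs). Default polynomial order K = 2, a standard
small-graph choice balancing receptive field and parameter count.

## Fusion classifier

Per band b: shallow conv X_S(b) = G(X, A_b) (width d1) and deep conv
X_D(b) = G(X_S(b), A_b) (width d2), each with its own θ coefficients and
feature map. Band fusion is a convex combination with learned weights,

    X_FS = p_θ X_S(θ) + p_α X_S(α) + p_β X_S(β) + p_γ X_S(γ),  Σp = 1,

with an independent weight vector for the deep branch. The simplex
constraint is enforced structurally by parameterizing p = softmax(q)
over four free logits, so non-negativity and Σp = 1 hold exactly after
every optimizer step — not approximately via projection. Fusion weights
are scalar per band and shared across nodes by default, matching the
fusion equation as written; a per-node variant (softmax over bands at
each node) exists behind `per_node_fusion` for the reading in which each
electrode weighs bands separately. Fused tensors pass ReLU, then a dense
layer to a common width (shallow and deep dense features are given equal
dimensionality so neither branch dominates by size), are concatenated,
and a final dense layer plus softmax yields class probabilities trained
with cross-entropy. The ablation grid covers shallow/deep/both ×
fused/cascade, where "cascade" concatenates the four band branches
instead of weighting them.

The network is small (≈ 10⁴ parameters at the default dims d1 = d2 = 16,
fc1 = 32), so forward and backward passes are written directly in numpy
and optimized with Adam (lr 1e-3, 100 epochs, batch 64, seeded shuffling
and initialization — training is bit-deterministic given the seed).
Analytic gradients are validated against central finite differences for
every variant. Node features are z-scored per (band, channel) using
training-set statistics. Dimensions, optimizer and schedule are package
defaults chosen as ordinary small-network practice.

Evaluation is stratified 5-fold cross-validation at the segment level
(fold assignment seeded; every fold must contain every class), reported
as mean ± sd accuracy over folds with a pooled confusion matrix. A
paired-samples t-test compares per-fold accuracies of two variants;
zero-variance differences (e.g. identical fold accuracies) are flagged
as degenerate rather than returning a meaningless p-value.

## Synthetic-data generator

The generator defines the study conditions under which the package is
verified. Each trial is a stable VAR realization: every channel has a
lag-1 self-coefficient (default 0.45) giving realistic temporal
autocorrelation, and each planted coupling (source, target, lag,
coefficient) adds an off-diagonal VAR term. Stability is checked at
construction via the companion-matrix spectral radius; an unstable
specification is rejected with the offending radius. On top of the VAR
component, each band carries filtered-white-noise oscillations
(unit-variance, scaled to osc_sd = 1.0); class membership multiplies one
band's oscillation variance on a chosen channel subset. Ratings are
emitted as 3 (low) or 7 (high) so threshold-5 binarization is
unambiguous. Ground truth returned alongside the data: the per-band
planted adjacency (identical across bands, since VAR coupling is
broadband), the informative band, and the per-trial classes.

The reference study (`beta_band_study_spec`) uses 8 channels, 80
ten-second trials (400 windows at the default segmentation), couplings
0→1 (lag 1, 0.6) and 2→3 (lag 2, 0.6), and β-band variance doubled on
channels 0–3 for the high class. The full 32-channel, 60 s geometry is
the generator's default and is exercised where dimensioned counts matter
(e.g. the 32×32×k retention rule); the smaller study keeps the
verification experiments to minutes on one CPU.

What the generator does *not* emulate: volume conduction, ocular/muscle
artifacts, non-stationarity across a session, 1/f background spectra,
and inter-subject variability. Passing tests therefore demonstrate that
the estimators and the classifier recover planted causal and spectral
structure under the stated noise model — not that comparable accuracy
is attainable on real recordings.

## Numerical choices and edge cases

- Non-integer window sample counts round half-up.
- GC fits guard against division by zero with a floor on the full-model
  RSS; in-sample F is ≥ −1e-10 by nesting.
- The normal-equation gram solves fall back to least squares if a
  submatrix is numerically singular.
- λ_max floor 1e-6; zero adjacency yields L̃ = −I.
- Softmax computations subtract the row maximum; cross-entropy clips
  probabilities at 1e-12.
- Fixture arrays are stored as little-endian float32; reading is exact
  at that precision.

## Known limitations

Pairwise (not conditional) Granger causality: a common driver induces
spurious pairwise edges; rank-based thresholding mitigates but does not
remove this. Time-domain GC only — no spectral (frequency-resolved)
causality. The asymmetric-Laplacian Chebyshev filter is a pragmatic
extension without the spectral guarantees of the symmetric case. The
fusion weights are identifiable only up to the scale freedom absorbed by
the per-band feature maps; in practice the informative band's weight
dominates on the reference study, which is the property verified.
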