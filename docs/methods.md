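# Methods

## The estimation problem

A sensory neuron is modelled as responding to the recent stimulus history
`x_t` (a lagged, channel-stacked vector of length `D = n_lags * n_channels`)
with a binary output `y_t ∈ {−1, +1}` (spike / no spike in bin `t`).  Two
generative pictures are used throughout:

* **Linear–nonlinear–Poisson (LNP):** a rate `r_t = g(k·x_t)` with a
  monotone static nonlinearity `g`, Poisson counts per bin, labels obtained
  by collapsing counts to spike/no-spike.
* **Binary noisy threshold:** `y_t = sign(k·x_t + η_t − θ)` with Gaussian
  threshold noise `η_t ~ N(0, σ²)`.  The implied `P(spike | z)` is the
  Gaussian CDF `Φ((z − θ)/σ)`; varying σ sweeps the effective nonlinearity
  from step-like to nearly linear.

The receptive field (RF) is the direction of `k`.  The overall scale of `k`
is not identifiable separately from the nonlinearity, so all accuracy
measures (Pearson filter correlation, angular error) are scale- and
sign-invariant.

## Classification-based RF estimation (CbRF)

The estimator treats RF recovery as large-margin binary classification of
spike-eliciting vs non-spike-eliciting stimulus vectors.  With margins
`m_t = y_t (k·x_t − θ)` it minimizes the convex objective

    J(k, θ) = ½‖k‖² + C Σ_t w_{y_t} max(0, 1 − m_t)²,   C = 1/(2λT),

an L2-regularized squared hinge loss.  Design choices:

* **Inverse-prior class weights** `w_{+1} = 1/(2p̂₊)`, `w_{−1} = 1/(2p̂₋)`
  equalize the influence of the (sparse) spike class and the non-spike
  class; balanced classes give unit weights.  This normalization makes the
  trivial-threshold limits of the weighted 0/1 error equal to ½ for both
  classes, and at the optimum the θ-stationarity condition forces the
  weighted hinge-residual masses of the two classes to balance exactly —
  both identities are asserted in the test suite.  Without the weights, and
  with spike probabilities below ½ everywhere (the usual sparse-spike
  case), the unweighted 0/1-optimal rule is the constant "no spike"; the
  unweighted surrogate then degenerates toward plain least-squares
  regression of the labels and inherits the spike-triggered average's
  biases under non-Gaussian stimuli.  This is the regime in which the
  weighting ablation (`weighting_ablation`) operates.
* **Parametrization** `C = 1/(2λT)` makes λ comparable across sample
  sizes.  θ (the spiking threshold / negated bias) is not regularized.
* **Solver:** trust-region Newton-CG (`scipy.optimize.minimize`,
  `trust-ncg`) with the analytic gradient and a Hessian-vector product of
  the generalized Hessian; both touch only margin-violating examples.  The
  objective is convex and piecewise quadratic, so the optimum is unique for
  λ > 0; a finite-difference gradient oracle and a derivative-free
  minimizer cross-check the solver in the tests.
* **Model selection:** λ over a log-spaced grid (default `10⁻³…10³`, 7
  points) by stratified K-fold (default 5) cross-validated ROC-AUC of the
  held-out projections; ties break toward stronger regularization.  Warm
  starts walk the grid strong-to-weak within each fold.
* The design matrix is centered per column before fitting; the reported
  threshold absorbs the shift so the filter applies to raw stimulus units.

## Baseline estimators

* **STA** — count-weighted mean of the centered stimulus rows at spikes
  (each spike counts, so multi-spike bins weigh by their count, the
  classical definition).  Direction-unbiased only for spherically symmetric
  ensembles; deliberately included to demonstrate its failure modes.
* **Ridge** — closed-form `(XᵀX + λI)⁻¹Xᵀy` on {0,1}-coded labels, λ by
  cross-validated projection MI (11 bins).
* **NRC** (normalized reverse correlation) — least squares restricted to
  the top-r eigenvectors of the stimulus covariance, r by cross-validated
  MI.
* **Poisson GLM** — exponential inverse link, L2 penalty on the filter
  (intercept free), trust-region Newton-CG on the penalized negative
  log-likelihood scaled per sample; linear predictor clipped at ±30 as a
  divergence guard; λ by cross-validated MI.  Unbiased exactly when the
  cell's nonlinearity is the exponential link — the contrast probed by the
  nonlinearity-robustness benchmark.
* **MID** (maximally informative dimensions) — gradient ascent on the
  plug-in histogram MI between projection and spike label (quantile bins,
  default 15), with the standard gradient built from per-bin conditional
  stimulus means and the derivative of the log density ratio.  The filter
  lives on the unit sphere (MI is scale-invariant).  Regularization is by
  early stopping on a held-out 20% split; restarts perturb the best
  solution with a geometrically decaying temperature, the first restart
  starting at the STA.  If spikes are too few for the requested bin count
  the bins are halved with a warning.

## Evaluation

* **ROC-AUC** of projections: rank-based spike/non-spike separability
  (ties ½); checked against exhaustive pair enumeration.
* **Projection MI**: plug-in histogram MI in bits over shared bin edges
  (default 11 equal-width bins; quantile option).  The plug-in estimate is
  positively biased at small held-out spike counts; comparisons therefore
  always use equal evaluation sizes across methods.
* **Nonlinearity reconstruction**: the per-bin ratio `P(z|spike)/P(z)`,
  proportional to the spike rate as a function of the projection.
* **Population protocol**: stratified 5-fold 80/20 evaluation of held-out
  projection MI per method, hyperparameters selected on the training side
  only.
* **Convergence protocol**: temporal prefixes (10…100% of the recording,
  never random subsamples) refit per method and correlated against the same
  method's full-data estimate; at 100% the correlation is 1 by
  construction.

## Synthetic stimuli and what they emulate

* **Skewed white noise** — i.i.d. Gaussian draws with positive amplitudes
  raised to `skew_exponent` (default 2) and negative amplitudes to its
  reciprocal, then re-centered: a long positive tail (sample skewness ≈ 2.6
  at the default) with an exactly diagonal auto-covariance.  Emulates
  asymmetric-intensity natural inputs while isolating the marginal
  asymmetry from correlations.
* **Whitened gratings** — random-orientation/frequency/phase sinusoid
  patches, ZCA-whitened (eigenvalue floor for rank-deficient ensembles).
  Second order is exactly white; the periodic structure leaves higher-order
  (multi-point) dependencies that bias second-order estimators.
* **FM tone complexes** — sums of unit-amplitude linear frequency sweeps
  with half-cosine ramps, in contiguous blocks (4 sweeps per 0.1 s block)
  or with continuous onsets thinned to an average concurrency of 3–4; the
  band-pass front-end (4th-order filters at log-spaced centers, Hilbert
  envelope, 20·log₁₀ compression floored 25 dB below the ensemble maximum,
  frame-averaged) converts waveforms to spectrograms.  Start/end
  frequencies are drawn uniformly in Hz.
* **Correlated spectrograms** — Gaussian noise shaped to a `1/f^α` temporal
  spectrum per channel, mixed across channels with a Gaussian kernel and
  optionally skewed pointwise.  A fully synthetic stand-in for
  speech/vocalization spectrograms: it reproduces 1/f temporal correlations
  and skewed marginals but not harmonic stacks, syllable rhythm, or
  comodulation — results on it support robustness claims, not claims about
  any specific natural corpus.

Ground-truth RFs are unit-norm: a biphasic difference-of-Gaussians onset
kernel in time (equal lobe amplitudes, negative lobe preceding positive),
an oriented Gabor on the lag×channel grid, or a separable spectral-Gaussian
× temporal-biphasic spectro-temporal onset.

All generators are reproducible: the same seed yields bit-identical output.

## Simulated cells

`calibrate_rate` resolves placement parameters expressed relative to the
projection distribution (sigmoid midpoint / hard threshold at a quantile,
slopes per projection SD) and then bisects the rate scale until the
expected spike count per bin matches the target (default 10% relative
tolerance).  The model-cell population draws nonlinearity parameters from
documented ranges (compressive exponent 0.3–0.8, power exponent {2, 3},
sigmoid slope 2–10 per SD, thresholds at the 90–98th percentile) and
randomizes filter placement; stratified cycling guarantees every requested
kind appears.

## Benchmark study conditions (and why)

Problem sizes are desk-scale: each recipe runs in seconds to a few minutes
on one core, and the test suite asserts medians over a few seeds where a
single draw would be noisy.

* **Skewed-noise benchmark** (`skewed_noise`): T = 50 000, 64 lags,
  skew exponent 2, sigmoid with slope 6/SD and midpoint at the 15th
  projection percentile, 0.3 spikes/sample.  The midpoint placement makes
  the nonlinearity genuinely saturating — most stimulus drive falls in the
  concave region.  That concavity, interacting with the positive third
  moment of the stimulus, is what depresses the STA's positive lobe (the
  bias reverses into an exaggerated positive lobe if the sigmoid is placed
  expansively); the rate keeps the saturated regime informative enough for
  accurate recovery.  CbRF reaches ≈ 0.96 correlation with the truth here,
  MID ≈ 0.99, and the STA's positive/negative lobe ratio ≈ 0.65 against a
  ground truth of 1.0.
* **Gratings benchmark** (`gratings`): 8 000 patches of 15×15, Gabor
  with envelope width 0.10 of the patch (so spurious structure has room to
  appear outside the support), 0.2 spikes/sample so the systematic STA
  artifact is not drowned by sampling noise at this reduced ensemble size.
  The out-of-support energy metric is the squared-mass fraction outside
  the true support (5% amplitude cut, dilated one pixel).
* **Nonlinearity robustness** (`nonlinearity_sweep` and the 20-cell
  comparison): correlated synthetic spectrograms, six nonlinearities from
  half-wave linear to hard threshold, 0.05 spikes/sample.
* **Weighting ablation** (`weighting_ablation`): 24 cells in the
  saturated-sigmoid sparse-spike regime described above, scored by
  fold-averaged 5-fold cross-validated MI — the same predictive-power
  protocol as the population analysis; a single 80/20 split is too noisy
  for a pairwise sign test at these effect sizes.
* **Convergence** (`TestConvergence` / `spikes_vs_convergence`): 20
  spectro-temporal cells, prefixes 10–100%, CbRF with a λ grid extending to
  10³ (small prefixes select strong regularization, which is what gives the
  method its low-variance small-sample behavior) vs MID.

## Numerical choices and degenerate inputs

* Solver tolerance `grad_tol = 1e-6` (∞-norm of the gradient); convexity
  makes the optimum unique, and non-convergence sets a flag and warns
  rather than failing.
* `sign(0)` in the threshold model is +1.
* Single-class inputs are rejected with actionable messages everywhere;
  stratified folding raises if a class has fewer members than folds.
* Ridge at λ = 0 on singular designs falls back to the pseudo-inverse with
  a warning; NRC clips ranks beyond the matrix rank with a warning.
* Zero-probability histogram bins are excluded from MI sums; empty marginal
  bins are omitted from nonlinearity curves.
* Whitening floors eigenvalues at 10⁻¹⁰ of the largest (with a warning) so
  rank-deficient ensembles remain usable.

## Known limitations

* Single-filter models only: cells with symmetric nonlinearities (zero
  STA) and multi-filter subspaces are out of scope, as are post-spike
  history effects and inter-neuron correlations.
* The weighted squared-hinge direction has a small intrinsic bias (≈ 0.02
  in correlation at T = 5×10⁴) under deeply saturating LNP channels with
  skewed stimuli — visible in the skewed-noise benchmark, where MID on
  identical data is closer to the truth.  The bias shrinks as the channel
  approaches the noisy-threshold generative model for which the surrogate
  is calibrated.
* Histogram MI values are plug-in estimates; absolute values at small spike
  counts are upward-biased and only comparisons at matched sizes are
  meaningful.
* The spectrogram front-end is a band-pass/Hilbert/log approximation to a
  gammatone filterbank, adequate for generating analysis ensembles but not
  a model of cochlear mechanics.
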