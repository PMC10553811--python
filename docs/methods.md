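# Methods

## Model and estimation problem

The estimand is a collection of probabilistic segmentation maps: for each
element `i` of an `N x N` cue grid (`N >= 3`), a vector
`p_i = (p_i[1], ..., p_i[K])` on the K-simplex giving the probability that
the observer assigns `i` to each of `K >= 2` segments.  The data are binary
same/different judgments on pairs of grid elements, collected in `N_b`
blocks over a set `P` of unordered, distinct pairs.  Conditional on the
maps, assignments at different elements are assumed independent, so the
same-segment probability for a pair is the dot product
`p_ij = p_i · p_j`, and each response is a Bernoulli draw with that
parameter.

Two data objectives are implemented:

* **BCE** — the summed Bernoulli negative log-likelihood over trials
  (pair probabilities clipped to `[1e-12, 1 - 1e-12]` inside logs);
* **SE** — the squared error `Σ_P (k_ij − p_i · p_j)²` against the
  empirical same-segment proportions `k_ij` (per-pair mean response
  across blocks).

When, for every tested element, the family of partner probability vectors
is linearly independent, the two objectives share their minimizers; SE is
the default, as a standard nonlinear least-squares problem on a
statistic (the proportions) that is sufficient for the Bernoulli model
with repeated pairs.

Counting degrees of freedom, the maps have `(K - 1) N²` free parameters,
so at least `(K - 1) N²` pairs must be tested.  The pair scheduler defaults
to `K N²` pairs: coverage of every element, per-element degree capped at
`ceil(2 T / N²) + 1`, and partners drawn preferentially at Chebyshev
distance `>= N/4` so that tested pairs are scattered rather than clustered.
Strictly minimal random designs are supported but can be rank-deficient by
chance; the extra `N²` equations of the default budget make recovery
reliable, which is why the deterministic-recovery validation uses the
default design.

## Spatial regularization

Nearby elements tend to share segments, so a quadratic penalty

    λ Σ_i Σ_k (p_i[k] − (G * p)_i[k])²

discourages maps that deviate from their local kernel average.  `G` is a
small kernel applied with replicated edges; the default `laplacian4`
(center 0, 4-neighbors 1/4) makes the residual a discrete 5-point
Laplacian.  `laplacian8` and a 3x3 binomial kernel are available, and any
odd-sized kernel can be passed.  The convolution is materialized as a
sparse linear operator so the penalty gradient (including edge-replication
terms) is exact.

Default weights: `λ = 10` in the simulation studies, `λ = 0` when the
point is to measure per-observer uncertainty unsmoothed (entropy
analyses), and `λ = 0` for parametric fits, where the model family itself
regularizes.

**Penalty scale under BCE.**  The SE objective carries one observation
per pair (the proportion) while the BCE objective carries ~`N_b`; a
penalty weight calibrated against SE would be ~`N_b` times too weak
against BCE.  When fitting BCE, the penalty weight is therefore multiplied
by the mean observations-per-pair.  With this convention the two
regularized problems have comparable prior-to-likelihood balance, and the
BCE/SE equivalence observed without regularization carries over to the
regularized fits (verified in the loss-equivalence study).

## Solver

Non-parametric fits use exponentiated gradient descent: multiplicative
update `p ← p · exp(−λ_r ∇ℓ)` followed by per-element renormalization,
which keeps every iterate strictly inside the simplex.  Iteration stops
when the objective changes by at most `ε = 1e-8`, or at `max_iter = 10000`
(capped at 4000 inside the canned studies; traces flatten well before that
at study problem sizes).  Gradients are closed-form (data terms plus the
sparse-operator penalty) and are checked against finite differences in the
test suite.

A fixed step size cannot serve both regimes: data-only gradients are O(1)
while `λ = 10` penalty gradients are an order of magnitude larger, and a
step that is fast for the former diverges for the latter.  The default
solver therefore backtracks: starting from `λ_r = 0.5`, the step is halved
whenever it would increase the objective and allowed to grow back (×1.2,
capped at the initial rate) after successful steps, making the loss trace
monotone at every regularization strength.  A plain fixed-rate mode
(`adaptive=False`) matching the textbook iteration is available; it is
monotone only for sufficiently small `λ_r`.

Initialization is i.i.d. symmetric Dirichlet (α = 1) per element with a
fixed seed.  The likelihood is invariant to label permutation, so fitted
channel order is arbitrary; all accuracy metrics align labels first (see
below).  `K = 1` is accepted as a degenerate case (all maps `(1)`, loss
constant).  Elements never touched by a tested pair are left at their
initialization (regularization aside) and reported with a warning.

## Evaluation metrics

* **MAE** — mean over elements of the L1 distance between estimated and
  reference K-tuples.  By default the reference channels are first
  permuted to minimize this distance; the total cost decomposes into
  per-channel costs, so the optimal permutation is an assignment problem
  (enumerated exhaustively for `K <= 6`, with lexicographic tie-breaking,
  Hungarian algorithm above that).
* **Entropy maps** — per-element Shannon entropy `−Σ_k p log p` in nats,
  with mean ± standard error across elements; zero exactly on one-hot
  elements, at most `log K`.
* **Non-empty segment count** — number of channels whose maximum
  probability anywhere exceeds a threshold (default 0.25).  Regularized
  fits with more channels than the data support drive the surplus
  channels' mass toward zero (observed maxima <~ 0.2, against >~ 0.7 for
  genuine segments at moderate uncertainty), so the true `K` is the
  largest fit `K` that leaves no channel empty.
* **Argmax segmentation** — ties broken toward the smallest label;
  labels are 1-based in files and user-facing objects.

## Synthetic ground truths and simulated observers

`sample_probmaps` draws `K` seed points by randomized farthest-point
sampling (each new seed uniform among the top decile of distance to
existing seeds) and labels each element by its nearest seed.  This yields
compact, roughly balanced Voronoi segments; uniform seeding occasionally
produces very small segments that strong regularization annihilates,
which would confound the segment-count analyses.  The one-hot labels are
then softened by an uncertainty profile (`level ∈ [0, 1]`,
`spatial_scale > 0`): Gaussian blur of the indicators with standard
deviation `level × spatial_scale` (uncertainty concentrates at segment
boundaries), renormalization, then mixing toward uniform by factor
`level`.  `level = 0` reproduces the one-hot maps exactly; mean entropy
increases monotonically with `level`; `level = 1` is maximally uncertain.
Study defaults: `level = 0.5`, `spatial_scale = 1.5` (moderate
uncertainty).

Simulated observers draw, for every tested pair, `N_b` independent
Bernoulli responses with parameter `p_i · p_j`, using one pair set shared
across blocks.  This emulates an idealized observer whose variability is
exactly the model's: no lapses, no learning or fatigue drift, no
response bias, and no spatial correlations in the noise beyond those
induced by the maps.  Passing validation on these data shows the
estimator inverts the assumed generative process at realistic data sizes;
it does not certify robustness to the response artifacts of real
observers.

Composite textures: a white-noise image is filtered in the frequency
domain by region-dependent oriented bandpass filters (log-Gaussian radial
profile, center 32 cycles/image, one-octave bandwidth; Gaussian
orientation profile around each region's center orientation), and the two
filtered fields are joined along a random smooth boundary (low-order
random Fourier series; hard 1-pixel transition; resampled until each
region holds 25–75% of the area).  Defaults place the two center
orientations at 80° and 100°; orientation bandwidth ~6° gives weakly
overlapping (low-uncertainty) textures and ~25° strongly overlapping
(high-uncertainty) ones.

## Parametric models and features

The multinomial logistic model `p_i[k] ∝ exp(ω_k · x_i + β_k)` (softmax
computed with max-subtraction) maps per-cell features to maps.  Only
differences `ω_k − ω_l`, `β_k − β_l` are identifiable.  Fitting minimizes
the same SE objective over pairs via L-BFGS-B with analytic gradients
(softmax pull-back), with optional random restarts; the variance
parametrization fixes `β = 0`, `ω_k = −1/σ_k²` and optimizes
`s = log σ²` unconstrained, keeping `σ² > 0`.  For `K = 2` the fitted
differential variance `σ_1² − σ_2²` per feature band is the interpretable
weight profile.  Features are not standardized by default (standardizing
would destroy the energy reading of `σ²`); optional z-scoring is available
for the free parametrization.

Feature extractors: per-cell mean RGB (D = 3), and oriented energy from a
log-Gabor bank — 36 orientation bands at 5° spacing (angular Gaussian,
σ = 0.8 × spacing), 4 dyadic scales from 0.25 cycles/pixel, squared
response moduli averaged over scales and over each cell's pixels.  The
wavelet family, scale count and normalization are package choices; any
bank measuring average oriented energy across scales serves the same
role, so band-profile shapes are comparable only qualitatively across
banks.

## Validation studies and problem sizes

The canned studies fix a ground truth, then repeatedly resample the pair
set, simulate responses, and fit — 50 resamples per condition by default
(the full protocol's 1000 are available via configuration), reporting
means with 2.5/97.5 percentile intervals.  Default scales: `N = 10`,
`K = 3` for the loss-equivalence, blocks (`N_b ∈ {1, 2, 4, ..., 128}`)
and uncertainty (`level ∈ {0.1, 0.3, 0.5, 0.7, 0.9}`, `N_b = 10`) sweeps;
`N = 12`, truth `K = 5`, fits at `K ∈ {3..7}` for the segment-count
study; `N ∈ {6, 10, 14, 18}` for the resolution sweep.  All studies are
deterministic given their seed.

## Known limitations

* The SE/BCE minimizer equivalence is exact only under the
  linear-independence condition; with scattered random designs it holds
  empirically but is not guaranteed pair-set by pair-set.
* Without regularization and with limited data, the data losses can be
  driven down while the maps drift away from the truth (MAE increases
  during optimization); regularization is the intended remedy, at the
  cost of a smoothing bias — at `λ = 10` on noiseless single-block data
  an isolated element near a boundary can be smoothed onto the wrong
  side.
* There is no principled rule for choosing `(λ, G)`; defaults were chosen
  for the study regimes above.
* Responses beyond binary (graded or multi-way judgments), adaptive pair
  selection, and grid-free designs are out of scope.
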