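# Methods

## The FCI model and its fit

For points drawn from a rotationally invariant distribution on a
*d*-dimensional hyperplane, centering on the barycenter and normalizing to
unit norm maps the sample onto the sphere S^(d−1).  The chord-distance CDF
of independent uniform points on S^(d−1) follows from the sin^(d−2) density
of the angular separation:

    rho_d(r) = I_{r²/4}( (d−1)/2, (d−1)/2 ),   r ∈ [0, 2],

with I the regularized incomplete beta function.  This is the "full"
correlation integral: unlike the Grassberger–Procaccia small-radius scaling
law it holds at all radii, which is what makes the estimator usable when
the sample is far too small to populate small neighborhoods (the sigmoid's
slope near its √2 midpoint carries the dimension information, and the
midpoint region is always well sampled).  The same function is often
written with a Gauss hypergeometric ₂F₁ factor; the incomplete-beta form is
numerically stable over the whole domain, so no special handling is needed
near r = 0 or r = 2 (the only clamp is a ≥ 1e−8 on the beta parameter so
the d → 1 limit, the two-point sphere S⁰ with CDF 1/2 on (0, 2), is taken
continuously).

We parametrize the model directly by the hyperplane dimension *d* (the
sphere is S^(d−1)), so the reported ID equals the fitted parameter.
Formulations that parametrize by the sphere dimension need a "+1"
compensation after the fit; folding it into the parametrization is
equivalent and removes a bookkeeping step.  The convention is pinned by
self-consistency: a uniform 2-D plane returns ≈ 2.00 and the d = 2 model
equals the circle arcsine law exactly.

**Fitting.**  The empirical correlation integral is evaluated at 64 radii
placed at equally spaced quantiles (0.5%–100%) of the pairwise distances —
quantile placement concentrates resolution where the sigmoid varies.  The
dimension is the only free parameter; it is found by a vectorized
log-spaced scan of d ∈ [1, 2000] (400 points — the residual surface can be
flat at high d) followed by bounded scalar minimization between the best
scan point's neighbors.  The goodness of fit (GoF) is the root-mean-squared
residual between the empirical and model curves; a non-convergent fit
returns GoF = ∞, never a silent number.

**Finite-sample centering correction.**  Subtracting the sample mean of P
isotropic points leaves pair cosines with expectation −1/(P−1) rather than
0 (E[x·x̄] = σ²/P), so squared chord distances are shifted by +2/(P−1)
relative to the model.  We subtract 2/(P−1) from squared distances before
fitting.  For P = 10⁴ the correction is invisible; in the undersampled
regime it is decisive: without it, 20 Gaussian points spanning 200
dimensions fit to d ≈ 57 (the shift masquerades as a shallower slope), with
it the median over 20 seeds is 199.5 (relative error 0.2%).  Keeping the
dimension as the only free parameter — rather than also fitting a radius
scale — matters for the local pipeline below: a free scale can absorb
curvature-induced distortion of the empirical curve, which would blind the
GoF reliability filter.

**Pair counting.**  All P(P−1)/2 pairs are used exactly up to P = 2·10⁴;
above that a seeded uniform subsample of at most 2·10⁸ pairs is drawn.
Callers can force a lower cap: the local pipeline uses 3·10⁵ pairs per
neighborhood, which bounds the CDF sampling error at ≈ 10⁻³ — an order of
magnitude below the GoF thresholds that matter (~10⁻²) — and keeps a
100-center × 12-scale run on 10⁴ points at roughly half a minute on one
CPU core.

## The local pipeline

Global FCI overestimates on curved manifolds.  The local pipeline fits FCI
on k-nearest-neighbor patches, which approximate the (flat) tangent plane,
across a grid of scales:

1. **Local estimates.**  M = 100 centers drawn uniformly without
   replacement (enough to cover a 10⁴-point dataset even at K ~ 100); for
   each center and each K in the grid, the FCI fit runs on the K nearest
   neighbors, centered on the *neighborhood's own* center of mass (the
   isotropy assumption concerns the sampled patch, not the query point).
   The default grid is 12 log-spaced integers from 50 to min(P/2, 10⁴).
   The grid deliberately stops at half the dataset: a "neighborhood"
   containing most of the points duplicates the global fit — on a curved
   manifold its GoF is excellent while its estimate is exactly the biased
   global one, and including it would corrupt the threshold rule below.
2. **GoF threshold.**  γ is the smallest per-scale 99th percentile of the
   GoF distributions (a "percentile at the scale with the lowest median
   GoF" variant is available as a configuration option).  Scales whose
   *median* δ (below) exceeds 2 are excluded from this computation: GoF has
   a scale-dependent sampling floor (more pairs → smoother empirical CDF),
   so the largest, already curvature-condemned scales would otherwise set a
   fit-quality bar below every genuinely local estimate.  On flat data all
   scales qualify and the rule reduces to the plain percentile rule.
3. **Reliability filter.**  An estimate is kept iff δ ≤ 2 and GoF ≤ γ.
   δ is the curvature proxy: the distance from the neighborhood's center of
   mass to its closest member, normalized by the mean nearest-neighbor
   spacing.  Flat patches give δ ≈ 1 at any anisotropy we tested; curved
   patches displace the center of mass off the manifold (an entire sphere
   puts it at the center, δ ≫ 2).  Calibration on isotropic flat 3-D data
   (10⁴ points, 100 centers, full grid) gives a 99th percentile of δ ≈ 1.8.
4. **Aggregation.**  The reported D* is the mode of the histogram of
   retained local estimates, with Freedman–Diaconis bin width — narrow
   enough to localize a tight unimodal peak to a few hundredths, wide
   enough to resolve the integer-separated peaks that curvature produces —
   and ties broken toward the lower bin.  The 10th/90th percentiles of the
   retained estimates (pooled across scales) give the plausibility band.

If every estimate is discarded (extreme curvature at all scales), the
global FCI estimate is reported with an explicit caveat flag; fewer than 10
retained estimates flags a low-confidence report.

**δ at large K.**  The numerator (min distance from the center of mass) is
always exact.  The denominator (mean nearest-neighbor spacing) is exact up
to K = 512 members or ambient dimension ≤ 15 (kd-tree); above, it is
estimated from 512 seeded anchor members, whose standard error of a few
percent is negligible against the δ ≤ 2 decision boundary.

## Comparison estimators

Linear: PCA-α (minimal number of components reaching a variance fraction),
participation ratio (Σλ)²/Σλ², and parallel analysis against
column-shuffled surrogates (pooled null-eigenvalue percentile, 100
shuffles, α = 0.05).  Geometric: correlation dimension (log–log slope of
the correlation integral between the 1st and 10th percentile of pairwise
distances), the k-NN maximum-likelihood estimator (harmonic aggregation
across points, the standard bias-corrected convention), and Two-NN (linear
regression of −log(1−F) on log μ through the origin, top 10% of
neighbor-distance ratios discarded).  Two-NN with decimation repeats the
fit on seeded subsamples of decreasing density and reports the plateau
(largest fraction within 5% of the next-smaller one) — subsampling dilutes
the small-scale noise that inflates plain Two-NN.  Cross-validated PCA
ranks axes by symmetrized cross-repetition covariance; independent noise
makes that spectrum symmetric about zero, so the magnitude of the most
negative eigenvalue serves as the per-axis noise floor, and the projection
keeps the smallest leading set of above-floor axes holding 99% of the
above-floor variance.

## Synthetic generators

All generators are bit-reproducible given (parameters, seed) and record
their ground-truth ID.

- **Flat families**: uniform patches rotated into higher ambient dimension,
  unit hypercubes, unit hyperspheres (oracle surface for the model), and an
  anisotropic family x → sign(x)|x|^(1+α) per coordinate that concentrates
  mass near the origin and axes while staying flat (α = 0 is isotropic).
  At α = 2 the density gradient is strong enough that the 99th percentile
  of δ can marginally exceed 2 (≈ 2.1 in our runs) — the δ filter is
  conservative by design, and this family is the stress test, not the
  typical regime.
- **Swiss roll**: (t cos t, y, t sin t), t ∈ [1.5π, 4.5π], y ∈ [0, 20],
  sampled uniformly with respect to surface area (inverse CDF of
  √(1+t²) dt on a fine grid), optional Gaussian ambient noise.  The global
  FCI estimate on this geometry measures ≈ 2.88; the printed value of a
  Swiss-roll benchmark depends on the (usually unstated) aspect ratio and
  radial sampling of the roll.
- **Latent neural trajectories**: d latent channels sampled iid per 50 ms
  bin from either a log-normal rate distribution (unit log-scale — a
  synthetic stand-in for heavy-tailed empirical cortical firing rates; the
  empirical distribution used in the original benchmark is not
  redistributable) or an equal-variance Gaussian, temporally smoothed with
  a Gaussian kernel of 50 ms s.d.; mixed into N = 96 ambient channels
  (≈ number of electrodes in a multielectrode array) by an iid standard
  normal matrix; optionally passed through the coordinate-wise saturating
  exponential y = (e^{αx}−1)/(e^{α}−1).  Coordinates are min-max mapped to
  [0, 1] — the map's natural domain — before the exponential; without
  this, mixed coordinates of variance ~ d would experience an effective
  nonlinearity of α√d.  Both embedding steps preserve the ID.
- **Repeated stimulus responses**: two repetitions sharing a rank-d signal
  with independent noise, the test bed for cross-validated PCA.

What the generators do *not* emulate: spiking discreteness, trial-to-trial
nonstationarity, and the specific heavy-tailed rate distribution of any
particular recording.  Passing recovery tests on these generators shows the
estimator handles high dimensionality, curvature, density gradients, and
monotone nonlinear distortion — not that any particular biological dataset
has a given ID.

## Cognitive-task networks

The rate RNN is the standard Euler-discretized model
r_t = (1−α) r_{t−1} + α·softplus(W_rec r_{t−1} + W_in u_t + b + ξ_t),
α = Δt/τ with τ = 100 ms, Δt = 20 ms, recurrent noise √(2/α)·σ_rec·N(0,1)
with σ_rec = 0.05, logistic readout, no constraints on the weights.  Inputs
are a fixation unit plus two 32-unit stimulus rings (Gaussian tuning of
width π/8 around preferred directions π/16·i, amplitude 0.8γ, summing over
simultaneous stimuli, input noise σ_in = 0.01); outputs are a fixation unit
plus a 32-unit response ring.  Twenty tasks are implemented in three
families (Go/Anti × forward/reaction-time/delay; decision-making with
contextual, multisensory and delayed variants; delayed match/non-match to
sample and to category).

Choices the task battery leaves open, fixed here and exposed in
`SimConfig`: epoch durations (fixation 300 ms, stimulus 500 ms, delay
500 ms, response 400 ms, 100 ms grace), response-ring targets as tuning
bumps with a 0.05 baseline and 0.8 fixation-output level, a loss mask of 1
during fixation / 0 in the grace period / 5 during the response, and
response decoding by the population-vector angle of the ring outputs
(correct within ±36°; a withheld response is decoded when the mean ring
output stays below 0.3).

Training is masked squared error with exact backpropagation through time
and Adam (batch 32, lr 3·10⁻³, early stop at 95% held-out accuracy), all in
numpy.  The full 256-unit configuration trains in minutes-to-hours per
task; the test suite exercises a 64-unit network on the reaction-time Go
task, which reaches > 90% accuracy in a few hundred steps and whose
trial-pooled hidden activity gives a local-FCI mode between 2 and 3 —
comfortably below both the ambient dimension and the noise-inflated Two-NN
estimate.  Reproducing per-task ID tables at full scale (10 trainings × 20
tasks × 200 trials) is supported by the same code path via the CLI but is
deliberately outside the default test run.

## Problem sizes and numerical choices

The benchmark analyses use 10⁴ points and M = 100 centers; recovery and
property tests in the suite run at 4·10³–8·10³ points with 20–60 centers,
sizes at which every qualitative result above is stable across seeds.
Percentile computations use numpy's linear interpolation; neighbor ties are
broken by index (stable sort); duplicate points are retained in k-NN
queries, collapsed with a warning in the MLE estimator, and excluded with a
count in Two-NN.  All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; the pipeline is bit-deterministic given
(points, K grid, M, seed).

## Known limitations

The δ > 2 criterion is conservative: manifolds curved gently at every scale
can pass it, leaving the (then slightly inflated) local estimates to the
GoF filter.  Very strong density gradients violate the local isotropy
assumption and show up as poor GoF rather than as curvature.  In sparsely
sampled peripheral regions local estimates are biased low — the histogram
mode is robust to a minority of such neighborhoods but the percentile band
widens.  The Euler discretization fixes Δt/τ = 0.2; stability of trained
networks at much larger α is not guaranteed.
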