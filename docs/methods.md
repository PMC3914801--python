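# Methods

This note records the scientific model behind `topomap`, the parameter
choices that matter, and the numerical decisions made where the underlying
definitions leave freedom. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Maps, measures, polarity

A sampled map is a set of `n` units with 2-D map-space coordinates `r_i`
(any consistent length unit; no grid is assumed anywhere) and a scalar
feature label `s_i`. Circular feature spaces (preferred angle and similar)
are declared explicitly with a period `T`; labels are canonically wrapped
into `(-T/2, T/2]` and all feature distances are circular,
`d_F = min(|Δs|, T - |Δs|) ≤ T/2`. Periodicity is configuration, never
inferred from data, because it changes every measure.

Most measures are instances of the generic pairwise-product functional
`C = Σ_{i<j} d_F(s_i, s_j) · d_M(r_i, r_j)` with different choices of the
two distance functions; each carries a *polarity* saying whether larger
(PC, SC, TC) or smaller (WL, PL, ZM, TP) values mean more topography. The
polarity registry is what orients the permutation test.

* **PC** — Pearson correlation between the `n(n-1)/2` feature distances
  and map distances. Undefined (typed error, never NaN) when either
  distance set has zero variance.
* **Multi-subject PC** — anatomical coordinate frames are not comparable
  between subjects, so only within-subject pairs enter; the correlation and
  its means run over the union of all subjects' pair lists. One subject
  reduces exactly to PC.
* **SC** — Pearson correlation of tie-corrected (mid-)ranks of the same
  two distance vectors.
* **TC** — map-space distance is the geodesic edge count in the Delaunay
  triangulation of the positions; a 1-D feature space has no triangulation,
  so the feature distance is the label rank difference. For periodic labels
  the ranks live on a circle and the difference is `min(|ΔR|, n - |ΔR|)`
  (our choice; the underlying definition is silent on circular features).
* **WL** — mean map-space distance over feature-adjacent pairs divided by
  the mean over all pairs. Units with identical labels are mutually
  adjacent and each is adjacent to all units carrying the nearest distinct
  label on either side; for circular labels adjacency wraps around. The
  normalization makes the value independent of map scale and units; the
  specific constant (mean-per-edge over mean-per-pair) is this package's
  choice of scale-free form.
* **PL** — WL with the two spaces' roles reversed: mean feature distance
  over map-space Delaunay edges divided by the mean feature distance over
  all pairs. A map with all labels identical gives 0/0; we define the
  result as 0 (a constant map has no feature structure left to disorder)
  and document rather than error, since the numerator is genuinely zero.
* **ZM** — for each Delaunay-neighbor pair, the number of units whose
  label lies strictly between the pair's labels; normalized by the number
  of Delaunay edges. "Strictly between" means endpoints are excluded: a
  unit whose label equals an endpoint label is not an intruder. For
  periodic labels intruders are counted along the shorter arc; exactly
  antipodal pairs use the arc ascending from the first endpoint
  (determinism). The arc length is computed with the same modular
  expression used for candidate labels, and an edge's own endpoints are
  excluded by index, so float rounding can never count an endpoint as an
  intruder.
* **TP** — Bauer–Pawelzik topographic product with the absolute value
  taken before averaging so the statistic is non-negative and usable in a
  one-sided permutation test: with `n^M_k(j)`/`n^F_k(j)` the k-th nearest
  neighbor of unit j in map/feature space,
  `Q1 = d_F(j, n^M_k)/d_F(j, n^F_k)`, `Q2 = d_M(j, n^M_k)/d_M(j, n^F_k)`,
  `log P3(j,k) = (1/2k) Σ_{l≤k} (log Q1 + log Q2)`, and
  `TP = (1/n(n-1)) Σ_{j,k} |log P3(j,k)|` (natural logs). When equidistant
  neighbors make an ordering ambiguous the value is the mean over 1000
  seeded random tie-break permutations (configurable). Distances are
  clamped to a relative floor of 1e-12 before the logarithms so duplicate
  positions or labels produce large-but-finite distortion values instead of
  infinities.

All seven measures are invariant under rigid motions and uniform scaling of
the positions and under adding a constant to all labels; this is enforced
by tests against naive loop-based reference implementations.

## Permutation tests

The null hypothesis is exchangeability of labels over positions. In
Monte-Carlo mode `m` label shuffles are drawn (default 10^4) and
`p = (b* + 1)/(m + 1)`, where `b*` counts shuffles at least as ordered as
the observed map under the measure's polarity. The add-one convention
counts the observed arrangement among the samples; it makes the test exact
(valid) and bounds p below by `1/(m+1)`. When the label multiset has at
most `m` distinct arrangements the full distribution is enumerated instead
and `p = b*/N` with the identity included — on a 5-point monotone line PC
attains its maximum for exactly the identity and the full reversal, giving
p = 2/120.

Two numerical details matter. First, each measure has a vectorized
permutation kernel evaluating a statistic that is a strictly monotone
transform of the measure under label permutation (pair-distance multisets
are permutation-invariant, so normalization constants drop); the observed
map goes through the same kernel, keeping comparisons internally
consistent. Second, "at least as ordered" is applied with a relative
tolerance of 1e-9, because symmetric rearrangements (e.g. a label reversal
on a symmetric configuration) can differ from the observed statistic by a
last-ulp summation-order artifact.

Randomness comes from a counter-based (Philox) generator keyed by the
user's seed; the same seed gives bit-identical results. Inside a
permutation test, topographic-product tie-breaks use one draw per shuffled
sample from the test's seed stream (the permutation distribution already
averages over samples); the reported observed TP uses the full tie-break
average.

The pooled multi-subject test shuffles the pooled label vector across all
subjects and deals it back preserving subject sizes, with the multi-subject
PC as statistic. Benjamini–Hochberg correction is delegated to
statsmodels; Bonferroni is a bare multiplication by the number of tests,
deliberately not capped at 1 so that hopeless results remain visibly
hopeless.

## Generative map models and the observation model

The simulation conditions are those the power analysis is defined on.

* **Linear** — `F(x, y) = a·x + b·y` on the unit square, `a, b ~ U(-1, 1)`
  (redrawn if `a² + b² < 1e-4`; only the gradient direction matters because
  label noise scales with the field's own SD, and a numerically flat field
  would leave the SNR undefined).
* **Angle** — two independent Gaussian white-noise fields are convolved
  with a zero-sum difference-of-Gaussians (mexican-hat) kernel with
  surround/center width ratio 1.5 and center sigma
  `scale_s × grid_size / 8` pixels (wrap-around boundaries keep the field
  stationary); the map is the argument of the resulting complex field,
  periodic with period 2π. `scale_s` therefore expresses the feature size
  as a fraction of the field width; doubling it doubles the measured
  autocorrelation length (tested).
* **Clusters** — Voronoi tessellation of `n_c` Halton seed points, each
  cell colored with an i.i.d. uniform circular label.
  `n_c = round(12.0 / scale_s²)`: the constant was calibrated once by
  matching the half-autocorrelation feature size of the colored
  tessellation to the angle map's at the same `scale_s` (agreement within
  10% over the calibrated scales), then frozen in source.

Observation: sampling locations are consecutive Halton points (bases 2 and
3, skip drawn uniformly from [0, 10^4) per seed) rejected to the disc
inscribed in the unit square, so that measure values do not depend on map
orientation. Labels are read from the nearest grid node of a 512² field
(finer grids change labels by O(grid spacing × gradient)); Gaussian noise
with `σ_noise = σ_F / SNR` is then added, where `σ_F` is the standard
deviation of the whole ground-truth field — circular,
`σ = sqrt(2(1 - R))` scaled by `T/2π`, for periodic fields — and periodic
labels are re-wrapped.

What the generator does *not* emulate: real maps degrade by warping,
fracturing and spatially correlated measurement error, not by i.i.d. label
noise; sampling sites in real experiments are chosen by the experimenter,
not low-discrepancy sequences. Passing tests therefore demonstrate
correctness and calibration of the statistics under the stated ensemble,
not robustness to every failure mode of real recordings.

## Power analysis

Power at `(measure, model, n, SNR)` is the fraction of replicates whose
permutation p ≤ α, each replicate drawing a fresh field, fresh Halton skip
and fresh noise — the estimate marginalizes over the map ensemble.
N80 is found by scanning the geometric grid
`n ∈ {5, 8, 12, 18, 27, 40, 60, 90, 135, 200, 300}` until power reaches
0.8, then bisecting to the smallest integer n that does. Falling short at
n = 300 raises an out-of-range signal, which the measure-comparison table
reports as a missing entry. The N80 standard error comes from a
nonparametric bootstrap over the per-replicate rejection indicators at the
bracketing sample sizes, log-interpolated to the 0.8 crossing.

Defaults are 200 replicates and 999 permutation shuffles per test. At
these settings a power estimate near 0.8 has binomial SE ≈ 0.028, so N80
itself is noisy by roughly its bootstrap SE; fold-ratios between measures
(the quantity of interest) are stable to well within the factor-of-two
scale on which measures differ. The acceptance script uses exactly these
settings at SNR = 2 on linear maps.

## Tuning curves and SNR estimation

Gaussian `A·exp(-(x-c)²/2w²)` and sigmoid `A/(1+exp(-(x-c)/w))` tuning
functions are fitted by bounded least squares (scipy `curve_fit`), width
bounded below (defaults 5° azimuth, 2 dB IID) to prevent overfitting
single-point peaks. Initialization: center at the stimulus of maximum
response (Gaussian) or maximum absolute discrete gradient (sigmoid),
amplitude at the maximum response, width at half the stimulus span; three
jittered restarts run only if the first attempt fails, and exhausted
restarts raise a fit-failure signal with the last optimizer error. For EI
(monotonic) cells both families are fitted and the lower-SSE one kept —
both have three parameters, so raw SSE is a fair criterion — with exact
ties going to the sigmoid, the canonical EI shape.

Characteristic labels: peaked cells use the Gaussian center; EI sigmoid
fits use the transition point; EI Gaussian fits use the 50%-of-maximum
crossing on the ipsilateral flank, `c + ipsi_sign · w·sqrt(2 ln 2)`, where
`ipsi_sign` is a per-dataset configuration flag (the recording hemisphere
fixes the side; it cannot be inferred from a single curve).

The bilinear SNR estimate fits `label ~ c0 + c1·x + c2·y` by least squares
and returns `sd(fitted)/sd(residual)`; a numerically perfect plane returns
`inf`. Applied to disc-sampled linear-map simulations this estimator
carries a known geometric bias of `sqrt(3)/2 ≈ 0.87` (the SD of a linear
field over the inscribed disc is smaller than over the full square used to
scale the noise), which is why the recovery test tolerance is 15% rather
than tighter.

## Degenerate inputs and tolerances

* Delaunay-based measures (TC, PL, ZM) raise a degenerate-geometry error
  when the positions' second singular value falls below 1e-10 of the
  position range (near-collinear or coincident sets); an opt-in flag
  applies deterministic jitter of 1e-9 × range with a caller-supplied
  seed instead, since silent jitter would be irreproducible.
* Duplicate positions are allowed wherever no triangulation is needed
  (PC, SC, WL, TP); TP handles the resulting equidistant-neighbor ties by
  its Monte-Carlo rule.
* Zero-variance distance sets (all labels equal under PC/SC, complete
  Delaunay graph under TC) raise typed undefined-measure errors.
* 3-D map spaces and multi-dimensional feature spaces are out of scope;
  the containers are written to allow the extension but only 2-D maps and
  scalar features are implemented and tested.
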