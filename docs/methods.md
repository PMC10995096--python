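# Methods

`lqci` reimplements a complete urban blue-green landscape quality
assessment pipeline: class-level landscape pattern metrics from categorical
rasters, a weighted composite quality index with level classification, and
a genetic-algorithm-initialized backpropagation network that predicts the
composite index, validated with standard error metrics and leave-one-out
cross-validation. This note records the models, the parameter choices that
matter, and the places where the design was genuinely open.

## Landscape pattern metrics

Rasters are single-band integer grids with square cells; a patch is a
maximal connected component of one class (8-connected by default,
configurable to 4, matching the FRAGSTATS convention). Components are
labeled with `scipy.ndimage.label`. For a class with `NP` patches covering
`A` cells in a landscape of `L` cells with cell edge `s` metres:

- **NP** — patch count; **PD** = NP / landscape area in km².
- **AREA_MN** — mean patch area, reported in hectares.
- **LPI** = 100 · (largest patch cells) / L, percent.
- **LSI** = 0.25 · E / √A, with E the total class edge length in cell-edge
  units. Edges where the class meets the grid boundary or nodata cells are
  counted (FRAGSTATS raster convention), so a full-grid class still has
  LSI ≥ 1.
- **AI** = 100 · g / g_max, where g counts 4-neighbour like adjacencies
  (each shared edge once) and g_max comes from the largest-integer-square
  construction: n = ⌊√A⌋, m = A − n²; g_max = 2n(n−1), plus 2m−1 if
  0 < m ≤ n, plus 2m−2 if m > n.

Degenerate inputs: an empty class reports NP = 0, PD = 0 and NaN for the
remaining metrics (undefined, not zero); a single-cell class has
g_max = 0 and AI is NaN. The published index table for the study area is
shipped as a fixture but is internally inconsistent (patch counts
incompatible with the printed densities and the 55.47 km² landscape), so
it is never used as a numeric target for this module; the module is
validated against brute-force enumeration oracles on randomly generated
rasters instead.

## Indicator system and composite index

The 29-indicator system (8 socio-economic, 9 ecological, 12 landscape
pattern) ships with its published weights in percent. The composite index
for year *i* is

    LQCI_i = Σ_j w_j · V_ij ,

where V_ij are min-max normalized indicator values — benefit direction
(x − min)/(max − min), cost direction mirrored. Weights are used exactly
as printed and are **not** renormalized: they sum to ≈ 55.9 %, and only
that reading makes the published truth series (28.77–43.72) attainable
from values in [0, 1]. Polarity defaults to benefit for every indicator
(the source gives no cost directions) and is configurable. A constant raw
column normalizes to 0.5 everywhere and is flagged rather than dropped —
one study input column (water area) is constant across years.

AHP machinery is included for deriving weights from pairwise comparison
matrices (principal right eigenvector, consistency ratio against Saaty's
random-index table, conventional CR ≤ 0.1 threshold); the published
weights are the canonical set since the underlying pairwise judgments are
not published.

Level classification maps a score x on a scale [s1, sn] to one of n
ordered levels via k = ceil((x − s1)/(sn − s1) · n), clamped to [1, n],
with k = n the best level (roman I) and k = 1 the worst (IV). With the
scale (s1 = 28.77, sn = 43.72, n = 4) this reproduces the published levels
for 7 of the 8 study years. The 2017 score (36.25) computes to ordinal
ceil(2.0013) = 3 → level II while the source prints III; no
rounding convention we tried reconciles it, so it is pinned in the test
suite as a documented discrepancy rather than guessed around.

## Network model and training

The predictor is a three-layer perceptron with 17 inputs, 6 sigmoid hidden
units and one output (115 free parameters), trained by full-batch gradient
descent on E = ½ Σ‖y − ŷ‖² with early stopping when E < R. Defaults follow
the study protocol: learning rate 0.001, target error R = 0.001. The
estimator owns its scaling: inputs are min-max scaled to [0, 1] per
feature, targets to [0.1, 0.9] so the sigmoid output unit can reach every
training target with slack for inverse scaling; predictions are reported
on the original scale.

Two choices were genuinely open:

- **Momentum.** Default 0.9 (classical heavy-ball). At lr = 0.001, plain
  gradient descent stalls near E ≈ 0.004–0.005 on the 8-sample study
  problem even after 200 000 epochs, i.e. the protocol's own stopping rule
  E < 0.001 is unreachable without momentum; the source motivates
  momentum-augmented optimization explicitly. With momentum 0.9 both
  models stop at E < 0.001 within ~40–60 k epochs.
- **Epoch cap.** `max_epochs` defaults to 200 000 — large enough that the
  stopping rule, not the cap, ends training under the defaults.

Initialization is uniform in (−1, 1) (matching the genetic search bounds),
seeded. Gradients are analytic and verified against central finite
differences. Training error becoming non-finite raises a divergence error
naming the epoch.

## Genetic initialization (GA-BP)

All weights and biases are flattened into one real-valued chromosome (v1
row-major, then b1, w2, b2), each gene bounded in (−1, 1). Fitness is
1/(1 + E) — positive, maximizable, strictly decreasing in E. Defaults are
the study values: population 20, 100 generations, crossover probability
0.3, mutation probability 0.1. Open operator choices, resolved as the
standard real-coded forms:

- **Selection** — roulette wheel (fitness-proportional).
- **Crossover** — arithmetic: children α·a + (1−α)·b and (1−α)·a + α·b
  with α ~ U(0,1) per pair, so children stay within bounds by convexity.
- **Mutation** — per-gene uniform resampling within (−1, 1). (The source's
  "adjusted by a value ≥ 1" cannot coexist with the −1 < w < 1 constraint;
  the bound-respecting reading is implemented.)
- **Elitism** — the best chromosome carries over unchanged (count 1), which
  guarantees the monotone best-fitness trace the study reports.

The best-ever chromosome becomes the BP initialization; BP then refines it
under the same stopping rule, so the final training error never exceeds the
GA's best error.

## Evaluation

Metrics (MSE, RMSE, MAE, MAPE, Pearson R) are computed on the original
(denormalized) index scale; MAPE is flagged undefined when any true value
is zero. The 70/15/15 split takes floors of the nominal fractions with
remainders assigned to training first (8 samples → 6/1/1). Leave-one-out
cross-validation follows CV(n) = (1/n) Σ MSE_i with one sample held out
per fold; each fold trains a fresh estimator (seed derived from the master
seed plus the fold index), and because the estimators fit their min-max
scalers inside `fit`, normalization statistics are fold-local — nothing
leaks from the held-out year.

### The leave-one-out gap

The published held-out MSE (1.2881) is not reproducible under the stated
protocol, and we report the measured value instead: median CV(n) over
master seeds is ≈ 26–39 (index-units squared). The structure of the gap is
informative. Folds that hold out an interior year (2016–2019) predict to
within ~1 squared unit. Folds that hold out an endpoint year are pure
extrapolation: with 2015 held out, the remaining targets span 35.65–43.72,
fold-local target scaling cannot even represent the true value 28.77, and
that single fold has median squared error ≈ 147. A 115-parameter network
interpolating 7 points has no basis for extrapolating a trend, and the
source's own printed prediction for 2022 (36.66 vs truth 43.72, squared
error ≈ 50) is itself incompatible with a CV of 1.2881. The defining
identity CV(n) = mean(MSE_i) is verified against brute-force fold
recomputation; the headline CV value is reported as measured.

## Synthetic data

The indicator-series generator emulates the study's yearly tables: each
indicator is intercept + slope·(year index) + independent Gaussian noise,
and the truth composite is computed from the generated matrix through the
same normalization and weighted-sum code path as the real pipeline, so
model-fitting tests have exact ground truth. Defaults mirror the study
shape (8 years, 17 indicators); the noise model is the simplest testable
structure (independent Gaussian per indicator). One degeneracy is worth
knowing: with zero noise every linear trend normalizes to the same ramp,
the normalized columns become collinear, and the generating weights are
unidentifiable from the matrix — weight-recovery checks therefore use
nonzero noise, where truth = V·w holds exactly by construction and least
squares recovers the weights to machine precision.

The raster generator grows patches by seeded region growing (an
aggregation knob interpolates between ragged uniform-frontier growth and
compact most-neighbours growth), keeps same-class patches 8-disconnected
by a one-cell moat, and reports the realized layout so metric oracles have
exact ground truth. It emulates categorical land-cover maps, not real
imagery: no classification error, no mixed pixels, no georeferencing.
Passing tests therefore demonstrate correctness of the metric and model
machinery on known-truth inputs, not remote-sensing fidelity.

## Problem sizes and determinism

The packaged study is deliberately small (8 years × 17 inputs), so full
training runs, 10-seed replications and the 8-fold leave-one-out loop are
all exact reproductions of the protocol, not scaled-down stand-ins.
Property suites use randomized small instances (rasters up to 30×30,
networks up to 5-8-2). Every stochastic stage — initialization, the
genetic search, splits, synthetic generation, per-fold seeds — draws from
a generator derived from one master seed, and end-to-end runs with the
same seed are byte-identical.

## Known limitations

- The 29-indicator raw matrix is only partially published; the composite
  pathway is exercised end-to-end on synthetic data, while the published
  truth series is consumed as given targets.
- Published aggregate metrics are not all internally consistent (see the
  leave-one-out gap above; the printed training MAPE also does not
  recompute from the printed prediction table). Bounds-style comparisons
  are made where the protocol supports them.
- The landscape-index fixture table is a best-effort reconstruction of a
  typographically damaged source table and is not used as a numeric
  target.
- Raster I/O covers ASCII grids and plain single-band TIFF; georeferenced
  formats are out of scope.
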