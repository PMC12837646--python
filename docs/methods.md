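# Methods

This note records the models, conventions and design choices behind the
package, and what its tests do and do not establish.

## Data

The bundled campaign is a 15-run subset of the 3×3×3 factorial over
extraction time (10/20/30 min), temperature (25/50/75 °C) and
sample-to-solvent ratio (10/15/20 mL/g), with 13 bioactivity responses
reported as triplicate means ± SD. Fixtures are hand-transcribed CSV/JSON
under `src/uaeopt/fixtures/` and spot-checked in the test suite; the ratio
is stored as the numeric mL-per-g value, a response printed with two
decimals is padded to three (PM, run 15: 0.740), and the significance
letter groups of the source tables are not stored (they encode an ANOVA
that is out of scope here). The published weight matrices of the three
surrogates are bundled as JSON with explicit shapes (W₁: hidden × inputs,
W₂: outputs × hidden) and activation identifiers; "Log" is read as the
logistic sigmoid and "Iden"/"Identity" as the identity map.

## Surrogate model and training

Each surrogate is a single-hidden-layer perceptron
Y = g(W₂ · f(W₁ · X + B₁) + B₂). The hidden activation f is applied to
W₁X + B₁ and the output activation g to the second layer — the binding
that matches the per-model activation declarations (tanh/identity,
tanh/tanh, logistic/identity for the 3-9-2, 3-10-6 and 3-10-5 networks).

Training minimizes the sum-of-squares loss in scaled space with BFGS and
exact one-hidden-layer backpropagation gradients:

* **Scaling.** Inputs are min-max scaled to [−1, 1]. Outputs are min-max
  scaled to the codomain of the output activation: [−1, 1] for tanh
  outputs, [0, 1] otherwise. Both are overridable; the scaling used by
  the original software is not recoverable, which is why forward passes
  through the *published* weights are checked only directionally (finite
  outputs, positive rank correlation with the measured response), never
  against the printed error table.
* **Split.** 60/20/20 train/test/validation by seeded shuffle with
  rounded sizes (15 samples → 9/3/3). Whether the original split was
  random or manual is unknown; a seeded random split is used.
* **Restarts.** Uniform [−0.5, 0.5] initial weights, independently seeded
  per restart; 200 restarts by default. This is a desk-scale stand-in for
  a much larger published topology search with the same best-of-restarts
  semantics. By default the best restart is the one with the lowest
  training loss (equivalently highest pooled training r², since the
  training sum of squares about the mean is fixed); `select_by="test"`
  scores restarts on the held-out partition instead.
* **Early stopping.** The BFGS iteration count is capped at 70, the epoch
  budget beyond which training on this dataset starts to overfit.
* **Performance.** Reported r² per partition is the pooled coefficient of
  determination 1 − SSE/SST in scaled space; a restart with non-finite
  loss is discarded and counted.

With 9 training points and 9–10 hidden units the networks interpolate the
training partition, so training r² ≥ 0.999 is the expected outcome; the
held-out partitions are small (3 points) and their r² is noisy and often
poor. This is faithful to the modelling protocol being reproduced, but it
means the *train-selected* networks are unreliable **between** design
points. Consequently the continuous-box genetic optimization
(`analysis/03`) refits with `select_by="test"`: restarts are scored on
held-out data, which suppresses interpolation noise and yields a selected
condition within one factor level of run 6 with a predicted response
profile matching run 6's measurements. The train-selected protocol is kept
wherever performance *on the design points* is the quantity of interest.

## Validation statistics

χ² = Σ(x_exp − x_pre)²/(N − n) with n = 2 constants by default: the value
of n is not stated alongside the formula, but the bundled published fit
table satisfies sse ≈ 15·rmse² and χ² ≈ sse/13 row by row, which pins
N = 15 and n = 2. Two rows of that table (ABTS, tyrosinase) are internally
inconsistent at printing precision — their printed RMSE implies an SSE
different from the printed SSE — and the consistency test reports exactly
those rows. MPE keeps the sign of the deviations; AARD takes absolute
values; both are reported in percent. r² is 1 − SSE/SST about the mean of
the experimental values. Correlations are Pearson on the 15 response
means (replicate-level data are not available) with two-sided t-test
p-values.

## Chemometrics

PCA standardizes each response (sample SD) before decomposition,
equivalent to an eigendecomposition of the correlation matrix — the only
defensible choice for 13 responses with heterogeneous units. Components
are ordered by decreasing variance and each loading vector is oriented so
its largest-magnitude entry is positive. On the bundled campaign this
yields PC1 = 45.6 % and PC2 = 18.9 %. The first agrees with the reference
value (46.15 %) within a percentage point; the second does not (printed:
15.66 %). An extensive probe — covariance PCA, transposed data, log and
rank transforms, every 12-response subset, adding the three factors or the
SD columns as variables, simulated replicate-level data — found no
convention that reproduces both printed percentages, so the mismatch is
reported honestly in the comparison table rather than absorbed by a
convention chosen to fit.

Hierarchical clustering uses complete linkage on City-block (Manhattan)
distances over the **raw** response means: in raw units the final merge
isolates run 6 at height ≈ 113, reproducing its reported separation
(> 100), which is unreachable after standardization. Cluster labels from
a k = 3 cut isolate {6} and group runs {1, 2, 4, 5, 13, 14} together.

## Optimization and ranking

The genetic search is NSGA-II-style: simulated binary crossover
(η = 15), polynomial mutation (η = 20, rate 1/3), binary tournament on
(rank, crowding), fast non-dominated sorting, population 100, and a Pareto
front capped at 50 points by crowding-distance thinning that always keeps
the per-objective extremes. The run stops once the leading front is
unchanged for 20 generations (cap 100), so generation counts are outcomes
of convergence, not inputs. Exact dominance filtering
(`pareto_front`) is verified against a brute-force double-loop oracle.

The standard-score ranking defaults to the min-max convention: per
response, (x − min)/(max − min), reversed for minimized responses,
averaged over all 13 responses. Under this convention run 6 scores 0.800,
matching the reference value 0.794 to within rounding of the inputs;
classic z-scores (sample or population SD) produce the same winner but a
different numeric score (≈ 1.23–1.27), so the min-max convention is the
one the reference value was computed under. All 13 responses default to
"maximize" (higher bioactivity is better), overridable per response.

## Synthetic campaigns

The generator draws replicate measurements from quadratic-with-
interactions surfaces plus independent Gaussian noise. Quadratics are the
simplest family with an interior optimum like the real campaign's; the
bundled default per response is a least-squares quadratic fit to the 15
measured means, affinely rescaled so its range over the design equals the
measured range, with noise at the median printed SD. What the generator
does **not** emulate: replicate correlation across responses (nothing in
the data constrains it), non-Gaussian assay error, and any
extraction-kinetics mechanism — it is a statistical stand-in, so passing
recovery tests show the pipeline recovers optima of smooth noisy
surfaces, not that the biochemical conclusions are correct.

The recovery experiment simulates a 27-run triplicate campaign, fits a
4-hidden-unit surrogate (80/10/10 split, 20 restarts scored on the test
partition) and maximizes it with the GA. The calibrated TPC surface has
three near-equal local optima (≈ 1 response unit apart against a
replicate-mean noise of ≈ 0.13), which bounds the achievable hit rate;
the deliberately small, held-out-selected surrogate recovers the true
optimum within one factor level in at least 90 % of the 20 seeded
campaigns of the recovery test (20/20 at the default seeds).

## Numerical choices and problem sizes

Grid argmax ties break toward the lowest time, then temperature, then
ratio. Min-max scaling of a constant column maps to the interval
midpoint, z-scoring maps it to 0 (with a warning); the inverse returns
the original constant. Scaled values outside the fitted range are
extrapolated linearly, never clipped, so optimization can probe the box
edges. Dendrogram and Pareto operations are deterministic; every
stochastic step (split, restarts, simulation, GA) is driven by explicit
seeds, and pipeline outputs are byte-identical across reruns at the same
seed. Default problem sizes — 200 training restarts, GA population 100
with a 100-generation cap, 20 recovery seeds, 50-point Pareto instances in
the property tests — keep a full run in the low minutes on one CPU while
preserving the best-of-restarts and convergence semantics of the original
protocol.

## Known limitations

* The printed PC2 percentage (15.66 %) is not reproducible under any
  standard PCA convention tried; see above.
* The published goodness-of-fit table cannot be regenerated from the
  published weights because the original normalization is unstated; the
  package exposes the forward pass and validation battery so the
  conventions can be probed, but promises no match.
* Two rows of the published fit table are internally inconsistent at
  printing precision (ABTS, tyrosinase).
* Held-out partitions of a 15-run campaign contain 3 points; test and
  validation r² values are therefore highly variable and should not be
  over-interpreted.
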