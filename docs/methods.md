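# Methods

## The problem

Vis/NIR reflectance spectroscopy can estimate leaf chlorophyll without
destroying the leaf, but only through a calibration model, and the model
is only as good as the calibration set behind it. Chlorophyll reference
values come from wet chemistry (solvent extraction + spectrophotometry),
which is slow and destructive, so one wants the *smallest* calibration
subset that still represents the population the model must serve. This
package implements that workflow — spectra preprocessing, sample
selection, a representativeness statistic, two calibration models and
their assessment — together with a synthetic data generator emulating
the study design it was built around: 5 plant species sampled monthly
February–November with 7 replicates (350 samples), chlorophyll roughly
0.79–3.03 mg g⁻¹.

## Preprocessing

Reflectance R ∈ (0, 1] is transformed to absorbance A = log₁₀(1/R)
(Beer–Lambert heuristic: approximately linear in absorber
concentration), then each spectrum is smoothed along wavelength with a
Savitzky–Golay filter, polynomial order 1, window 15 bands — a local
least-squares line evaluated at the window centre. Order matters:
absorbance first, smoothing second. Polynomials up to the filter order
are fixed points; the filter is linear.

Edge handling is not uniquely defined by the method; the default
(`polyfit-extend`) evaluates the edge-window polynomial at the edge
positions so no bands are lost, with `shrink-window` (symmetric window
shrinking) as the alternative. The filter requires a uniform wavelength
grid (relative tolerance 1e-6) and refuses non-uniform input rather than
silently resampling. Smoothed absorbance is floored at 0 (edge
extrapolation can undershoot on near-zero baselines); smoothed
reflectance is clipped into (0, 1]. Spectra ends are kept by default; an
optional trim to a half-open nm interval is available.

## Kennard–Stone selection

KS picks well-spread samples deterministically: the globally most
distant pair first, then whichever point maximises its minimum Euclidean
distance to the selected set. Ties break to the lowest index
(lexicographically smallest pair for the opener), making the output
unique. Selection runs in principal-component space retaining 99% of the
spectral variance by default (`raw-spectra` available); distances are
Euclidean. One KS pass yields nested subsets for free — the first *m*
selections are exactly the KS selection of size *m* — which produces the
serial ladder 60, 100, 140, 180, 220, 260 from the 280-sample
calibration pool. The 280/70 calibration/validation split is itself a KS
selection from the 350-sample pool (the unselected 70 validate).

## The MSD representativeness statistic

For subset size *i*, each retained PC *j* contributes the squared
Euclidean (L2) distance between two kernel density estimates,

    d²_j = ∫_a^b ( P_p(x_j) − P_s(x_j ∈ ss) )² dx_j ,

where P_s is the Gaussian KDE of the subset's scores on PC *j* and P_p
that of the validation population's; the statistic is the mean over the
first k PCs (default k = 6). Numerical choices:

* **Bandwidth** — Silverman's rule, 0.9·min(sd, IQR/1.34)·n^(−1/5),
  computed on the *population* scores per PC and reused for the subset
  density, so d² compares distributions rather than bandwidth choices.
* **Integration range and grid** — the union of both score ranges padded
  by 3 bandwidths, composite trapezoid on 512 equally spaced points
  (doubling the grid changes d² by < 1e-6 at these settings; the
  single-point case matches the closed-form Gaussian overlap integral
  exp(−Δ²/4h²)/(2h√π) to 1e-6 at 2048 points).
* **PCA** — fitted on the calibration set only, mean-centred, with
  validation scores obtained by projecting onto the calibration
  loadings; this avoids leaking validation structure into the score
  space.
* **Nomination** — the paper-style elbow is made explicit: the smallest
  size whose msd is within 10% (relative) of the sweep minimum. The
  rule is deterministic given the sweep.

MSD is non-negative, zero iff the per-PC densities coincide on the grid,
and invariant to PC ordering.

## PLSR

PLS1 by NIPALS; with a single response the inner loop is closed-form per
component (w = X'y/‖X'y‖, t = Xw, p = X't/t't, q = y't/t't, deflation of
X and y). Predictors are mean-centred, never variance-scaled (all bands
share absorbance units — the spectroscopy convention). The coefficient
path B_k = W_k(P_k'W_k)⁻¹q_k gives predictions at every candidate LV
count from one fit, which makes exact leave-one-out CV affordable at
calibration sizes ≤ 280; the LV count minimising LOO RMSE wins (ties to
the smaller count), with `max_lv` default 20, clipped to the data rank
with a warning. Folds whose rank ends early carry their last reachable
error forward. With all LVs the predictor equals OLS on full-rank data;
score vectors are mutually orthogonal and the X-residual is orthogonal
to all scores (both asserted in tests, along with an independent
cross-check against scikit-learn's unscaled PLSRegression).

VIP per wavelength j uses SS_a = q_a²·t_a't_a (the y-variance captured
by LV a): VIP_j = √(p·Σ_a SS_a w_ja² / Σ_a SS_a) with unit-norm w_a;
mean(VIP²) = 1 is an identity and VIP > 1 flags informative bands.
`important_bands` turns the VIP curve into maximal nm intervals above a
threshold, with an optional merge gap. Both the VIP curve and the raw
regression-coefficient curve are reported; VIP carries the threshold-1
convention.

## Cubist-style model

A re-implementation of the published Cubist/M5 mechanism — model trees,
committees, instance-based correction — not a clone of the proprietary
code. Design choices, each configurable:

* **Split scoring.** A split on feature f at threshold t is scored by
  the summed residual SSE of simple linear regressions of y on f fitted
  separately on each side, against the parent's best single-feature
  fit. This is the variance reduction that matters for trees with
  linear models in the leaves: a mean-based score cannot see a slope
  kink (both sides of y = −|x| have equal means). Splits must remove at
  least `min_gain` = 5% of the parent's fit SSE, keep `min_leaf` = 10
  rows per side and stay within `max_depth` = 8; pure-noise targets
  therefore stay at depth 0. On wide spectra the split search is
  restricted to the 256 highest-scoring candidate features.
* **Node linear models.** Every node fits PLS1 on its candidate
  features (all wavelengths by default; optionally the split path plus
  a screened subset). On narrow, full-rank problems this *is* ordinary
  least squares; on p ≫ n spectra the LV count is capped at
  `model_lv` = 15 and n/3 and chosen by a striped (deterministic)
  3-fold internal CV, which keeps small leaves from interpolating and
  noise-averages across collinear bands the way any competent p ≫ n
  calibration must.
* **Pruning.** Reduced-error pruning, bottom-up: a subtree collapses to
  its node when the node model's internal-CV RMSE is no worse than the
  size-weighted mean of its children's estimates. (Pessimistic
  *training*-error pruning cannot collapse subtrees whose leaves
  interpolate — a zero-residual leaf looks perfect however it is
  penalised.)
* **Smoothing.** Predictions are blended leaf-to-root with the M5 rule
  (n_child·child + k·parent)/(n_child + k), k = 15; k = 0 disables it.
* **Committees.** Tree m+1 trains on residual-reflected pseudo-targets
  y − (ensemble_m(x) − y); the ensemble predicts with the member mean.
  A c-member committee is a prefix of a longer one, which the grid
  search exploits.
* **Nearest-neighbour correction.** The k nearest training spectra
  (Euclidean) each contribute y_i + f(x) − f(x_i); their mean is
  averaged with the raw ensemble output with weight w_nn = 0.5
  (the mechanism description says "averaged" without weights); k = 0
  disables the correction.
* **Grid search.** Committees {2, 4, 6, 8} × neighbours
  {10, 20, 30, 40} under 10-fold CV with a single seeded fold partition
  shared by all 16 cells (fold hash recorded); lowest mean CV RMSE wins,
  ties to fewer committees then fewer neighbours; the winner is refitted
  on all rows. Each fold fits the maximal committee once and evaluates
  all cells from prefixes.

## Evaluation metrics

R² = 1 − SSE/SS_tot, RMSE = √(mean squared residual) (RMSEP on the
validation split), RPIQ = IQR(obs)/RMSE with linear-interpolation
(type-7) quartiles, and bias = MBE = mean(pred − obs) — one explicit
sign convention for both names (published reports sometimes flip one of
the two without defining either; this package emits one number under one
convention rather than imitating the ambiguity). Constant observations
leave R² and RPIQ undefined (reported as missing with a warning, not an
error). Group summaries report mean ± SE (sd/√n) of predictions and
observations per species and per month; singleton groups have undefined
SE.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes —
it is a light-weight additive-absorbance model, deliberately not a
radiative-transfer code (PROSPECT-class physics is out of scope; the
pipeline only needs chlorophyll-correlated features in the bands the
field names):

    A(λ) = baseline_species(λ)
         + β_vis · chl · B_vis(λ)            # 500–640 nm, raised cosine
         + β_nir · chl · B_nir(λ)            # 740–1100 nm, raised cosine
         + w · [G(λ; 1450, 45) + G(λ; 1940, 45)]
         + ε(λ),  ε ~ N(0, σ_A²) iid,  R = 10^(−A)

* **Chlorophyll**: chl = species_mean × seasonal(month) + N(0, σ_c),
  clipped to [0.79, 3.03] mg g⁻¹. Species means (1.47, 1.95, 1.88,
  1.10, 1.77 mg g⁻¹) are the field study's; the seasonal factor is a
  cosine with amplitude 0.25 peaking in August. σ_c = 0.18 mg g⁻¹ was
  chosen once so that the overall calibration-set mean and SD land near
  the field summary (≈1.6 and ≈0.46 mg g⁻¹); the generated 280-sample
  KS calibration set reproduces both within 15%.
* **Pigment bands** are raised cosines compactly supported on exactly
  500–640 and 740–1100 nm, so band-recovery tests have exact ground
  truth. β_vis = 0.22 and β_nir = 0.10 absorbance per mg g⁻¹ give
  realistic band depths relative to the ≈0.45 baseline.
* **Species baselines** are smooth seeded curves (shared gentle slope
  plus four wide random Gaussian bumps per species, sd 0.06); one
  species carries an extra 1200–2400 nm excursion mimicking the one
  visibly deviant species in the field data.
* **Water** w ~ N(0.35, 0.08²) per sample, independent of chlorophyll
  by default, with a correlation knob to study water confounding.
* **Noise** σ_A = 0.005 absorbance units by default — a realistic
  bench-spectrometer floor after spectrum averaging.
* Absorbance is capped into [1e-3, 4] (clipping counted and warned), so
  reflectance stays in (0, 1] by construction. All randomness derives
  from a root seed through named substreams (crc32 of the consumer
  name), so adding a consumer never perturbs the others; regenerating a
  fixture with the same seed is byte-identical.

**What the generator does not emulate** — and hence what passing tests
do *not* show about field data: per-sample scattering/structure
variability beyond iid noise, detector splice artifacts, nonlinear
pigment–reflectance saturation, water–chlorophyll correlation (off by
default), and instrument drift. Because the synthetic
absorbance–chlorophyll relation is exactly linear given species and
water, both calibration models operate near the noise floor (validation
R² ≈ 0.9999 at default noise) rather than at the field study's ≈0.7;
the synthetic runs exercise correctness and ordering (the Cubist-style
model edges out PLSR, as in the field study), not field-level accuracy.

## Pipeline

`run_pipeline` chains the stages (simulate/ingest → preprocess → KS
split → MSD sweep → fit PLSR + Cubist on the nominated subset →
evaluate → report) into one run directory containing the preprocessed
spectra, id lists, MSD sweep table, serialized models, evaluation
reports (JSON + TSV), per-group tables and four figures (PC score
densities + MSD curve, predicted-vs-observed, VIP, monthly trend). The
YAML config mirrors the CLI flags; CLI overrides file. Every default
actually used (bandwidth rule, k, grid size, fold seed, nominated size)
is logged. Reruns with the same config and seed are byte-identical in
all text reports. When the calibration pool is too small for the study
ladder or the 10-fold grid (tiny smoke runs), the subset ladder is
scaled to the pool and the Cubist stage falls back to a single modest
cell — both logged.

## Problem sizes used in tests

The test suite runs the full 350 × 2151 study design for the end-to-end
and sweep checks (the sweep uses 20 seeded replicates), a 200-band
12-sample tiny design for smoke and determinism tests, and a 420-band
reduced grid for the noise-monotonicity check. These sizes are the
package's own choice of test scale; the complete suite runs in about a
minute and a half.

## Known limitations

* The Cubist-style model is a faithful mechanism re-implementation, not
  bit-compatible with the proprietary code; rule simplification beyond
  reduced-error pruning and categorical predictors are not implemented.
* MSD supports the L2 density distance only (no KL/Hellinger/
  Wasserstein variants, no joint 2-D densities).
* KS runs on a full pairwise distance matrix — fine for hundreds of
  samples, not intended for tens of thousands.
* The absorbance transform refuses R ≤ 0 and NaNs rather than imputing;
  proprietary instrument formats (.asd) are not parsed.
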