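# Methods

This note documents the models, numerical choices and limitations behind
`socgwr`, in the order the pipeline applies them.

## Profile stocks

Stocks use the fixed-depth approach over 0–100 cm: each layer contributes
`(c/100)·ρ·t·100` Mg/ha for its overlap `t` (cm) with the window, layers
straddling 100 cm pro-rata, layers below it nothing. No coarse-fragment
correction is applied — concentrations are taken on a fine-earth basis and
bulk density is an input, not modelled. The operation is additive over any
depth partition (property-tested), so re-layering a profile never changes
its stock. A profile with no layer inside the window is an error rather
than a zero: silent zeros would bias regional means.

## Outlier screening

Stocks are screened per ecoregion with the 1.5·IQR rule in a single pass:
quartiles by linear interpolation between order statistics, fences at
Q1 − 1.5·IQR and Q3 + 1.5·IQR, strict inequalities. The filter is applied
to raw (untransformed) stocks, before the train/test split and before the
Box-Cox fit, so the transform never sees values the analysis discards.
Regions with fewer than 4 observations pass through unfiltered (logged);
an IQR from 3 points is noise. Single-pass semantics are deliberate —
re-iterating after removal can cascade in small heavy-tailed regions — so
idempotence is not claimed.

## Box-Cox normalization

z = (y^λ − 1)/λ (ln y at λ = 0), fitted by maximizing the profile
log-likelihood −(n/2)·ln(RSS(λ)/n) + (λ−1)·Σ ln y over λ ∈ [−2, 2]: a
coarse grid at 0.01 resolution followed by bounded golden-section
refinement to 1e-4 (the likelihood is smooth but can be flat near the
optimum; the grid guards against the refinement sliding into a shoulder).
The likelihood is evaluated with `scipy.stats.boxcox_llf`, which is this
exact formula. Forward and inverse transforms use `expm1`/`log1p` forms,
stable as λ → 0; the inverse is defined only where λz + 1 > 0, and
predictions outside that domain become missing cells (counted and logged)
rather than clipped values. λ is fitted on the training partition only and
reused for test and map prediction, to avoid leakage.

## Predictor screening

Pearson pruning runs once on the initial correlation matrix of the
continuous predictors: pairs with |r| > 0.70 are visited in decreasing
|r| and the lower-priority member of each intact pair is dropped. The
priority list encodes which predictor's control on SOC is better
established (climate first by default). 0/1 indicator layers are exempt —
Pearson r between dummies is not meaningful collinearity evidence — and
one-hot encodings drop the reference class, so the dummy-variable trap
cannot arise. A logged Pearson-vs-Spearman comparison per predictor flags
monotone nonlinearity; it never triggers automatic transformations.

The split is simple random, n_train = floor(0.75·n), unstratified (a
stratified-by-region option was considered and rejected for the default:
the reference protocol gives no evidence of stratification and the
acceptance arithmetic 4559 → 3419/1140 is exact under plain floor).

Best-subset selection fits OLS (statsmodels) to every subset up to the cap
— exhaustive through 15 surviving candidates (2¹⁵ fits), forward stepwise
proposing one candidate per size beyond that, logged. A subset qualifies
only if the overall F-test and every slope's partial t-test reach p < 0.05
(the intercept is always present and is not tested — it is not a selected
predictor). Among qualifying subsets the winner has the largest adjusted
R², with a **practical-equivalence tie**: subsets within 1e-4 of the best
adjusted R² are treated as tied and the smallest (then lexicographically
first) wins. The tolerance is the package's parsimony rule: a marginally
significant predictor that moves adjusted R² by less than one part in 10⁴
is indistinguishable on any reported scale and only adds variance to the
downstream spatial fit. Without it, each pure-noise candidate enters
whenever its own t-test fires (≈5% each), which is the textbook stepwise
selection bias.

## GWR

Local estimator β̂(u) = (XᵀW(u)X)⁻¹XᵀW(u)z. Kernels: bisquare (default —
compact support pairs naturally with an adaptive neighbor-count bandwidth)
and gaussian (retained mainly for the analytic OLS limit). Distances are
planar Euclidean; a haversine metric is available when coordinates are
lon/lat degrees (the synthetic machinery is purely planar).

Adaptive bandwidth: at each focal point, b = distance to the k-th nearest
calibration point (the point itself counts), floored at 1e-9 × the
calibration bounding-box diagonal so coincident points never produce b = 0.
With the bisquare kernel the k-th neighbor itself gets weight zero; this
is the conventional convention and is applied consistently in fitting and
prediction.

k is selected by golden-section search over integers in [k_min, k_max]
(defaults p + 2 and n), memoized, each candidate evaluated by a full
leave-in fit; the returned k is the argmin of AICc over everything
evaluated, ties to the smaller k. AICc uses σ̂² = RSS/n and the focal hat
values h_ii = w_i·x_i(XᵀWX)⁻¹x_iᵀ; candidates with n − 2 − tr S ≤ 0 (or a
singular local system) count as +∞. The AICc(k) profile is not guaranteed
unimodal; golden-section is used as a bracketing heuristic and the memo
argmin keeps the choice well-defined either way.

Singular local systems get a ridge jitter (default 1e-8) added to the
normal-equation diagonal, logged, rather than dropping points — this keeps
the coefficient field complete where a kernel happens to cover a locally
constant indicator. With jitter disabled the singularity is an error
naming the point.

Prediction at a new location refits the local regression centered there
against the calibration set (same k or fixed bandwidth) and evaluates
β̂(u)·x on the transformed scale, then back-transforms. The back-transform
is the naive Box-Cox inverse; no smearing/bias correction is applied, so
mean stocks are conditionally median-type estimates and systematic
underestimation of high-stock regions is expected — the regional bias
table makes this visible rather than hiding it.

Correctness is anchored two ways: every local solve is checked against an
independent dense √w-scaled `lstsq` route (1e-8), and a gaussian kernel
with bandwidth 10⁶ × the domain diameter must reproduce global OLS
coefficients and fitted values to 1e-6.

## Scenario projection

Pure space-for-time: the fitted β̂(u) field is the model; per decade only
the named override layers (temperature, precipitation) replace their
baseline counterparts and every cell is re-predicted. Cells with any
missing predictor, or whose transformed prediction leaves the Box-Cox
inverse domain, are missing. Aggregation: total Tg = Σ stock·cell_area_ha
× 10⁻⁶ over non-missing cells, Pg = Tg × 10⁻³, planar equal-area cells.
The grand total equals the sum of regional totals to 1e-6 relative
(tested). Comparison against an external coarse SOC grid block-averages
fine cells into the coarse cell containing their center — a simple mean,
not area-weighted reprojection, adequate for co-registered planar grids
and documented as an approximation.

## Diagnostics

Regional bias is the signed mean of (predicted − observed) with percent
form |mean residual| / mean observed × 100 — the only definition
consistent with the published Everglades row (643.2/776.6 = 82.8%); the
sign is reported separately. Test R² = 1 − RSS/TSS is computed on the
back-transformed Mg/ha scale (the scale of the maps), with the
transformed-scale R² logged alongside. The coefficient PCA averages local
coefficients per region, standardizes columns, drops constant ones with a
warning, and eigendecomposes the correlation matrix; loadings are
orthonormal eigenvectors, region scores the projections, eigenvalues sum
to the retained column count.

## Synthetic landscapes

The generator emulates the statistical structure the analysis assumes, not
any real data product's marginals: Voronoi ecoregions from uniform seed
points (redrawn deterministically until all patches are non-empty and
4-connected); continuous predictors as Gaussian-filtered white noise
(kernel SD = correlation length in cells) standardized to mean 0/variance
1; categorical layers by quantile-slicing an independent smooth field,
one-hot with dropped reference; spatially varying coefficient surfaces;
response built as inverse Box-Cox of the local linear predictor plus
N(0, noise_sd²) noise, with per-row noise redraws (≤100) when the inverse
is undefined. For λ < 1 the convex inverse makes a symmetric transformed
response positively skewed, matching the unimodal right-skewed stock
distributions seen in field data. Profiles tile 0–100 cm with
Dirichlet(5) thicknesses and positive concentrations/densities rescaled so
the stock integral reproduces the site value to ~1e-9.

Default study conditions (the pipeline's data-generating process): a
landscape whose transformed-scale intercept is 20 ± 1 with climate
coefficients −1.2 ± 0.4 (temperature), +0.9 ± 0.3 (precipitation),
+0.6 ± 0.2 (NPP), zero for the remaining layers (decoys for screening),
λ = 0.5, noise SD 0.4. Climate trends are additive per decade for
temperature and multiplicative for precipitation (floored at zero only
when the baseline layer is physically non-negative; standardized anomaly
layers pass through unfloored).

Parameter-recovery experiments use a 60×60 grid (800 m), two continuous
predictors with a 3-cell correlation length, coefficient surfaces with a
15-cell correlation length, n = 800 sites and noise at 10% of the signal
SD. The predictor fields deliberately vary on a shorter scale than the
coefficient regimes: local slopes are identifiable only where the kernel
sees real within-window predictor variation. Problem sizes throughout the
examples and default configs (26–60 cells per side, 120–800 sites) are the
package's chosen demonstration scale — large enough for the spatial
structure to be estimable, small enough to run interactively.

What passing synthetic tests does *not* show: robustness to measurement
error in bulk density, to preferential (non-uniform) site placement, to
anisotropic or non-stationary predictor fields, or to real-world predictor
marginals; the generator produces none of these.

## Known limitations

* No mixed (partially global) GWR, no per-predictor multiscale bandwidths,
  no spatial autocorrelation testing of residuals.
* No bias correction on the Box-Cox back-transform (see above).
* Coarse-grid comparison is a block mean, not conservative remapping.
* The bandwidth search trusts the memoized AICc argmin on a possibly
  multimodal profile; a full grid sweep over k is available simply by
  setting k_min = k_max repeatedly, but is not the default.
* Best-subset selection beyond 15 surviving candidates is heuristic
  (forward stepwise); with the default synthetic predictor pools this
  branch is exercised only in tests.
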