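# Methods

This note documents the statistical content of `migsim`: the models and
procedures it implements, the defaults and why they were chosen, what the
synthetic generator does and does not emulate, and the numerical and
design decisions a user should know before trusting output.

## 1. Flow data model

Flows are stored as nonnegative **reals**, not integers. Empirical
bilateral flow series are frequently themselves estimates (harmonised or
model-based counts), and row calibration necessarily produces
non-integers. The diagonal of every origin–destination (OD) matrix is a
structural zero: staying put is not a flow, and no record with
`origin == destination` is accepted.

Location ordering is lexicographic unless an explicit order is supplied;
one ordering is used for every matrix in an analysis. Missing dyads in an
incomplete panel are filled as zero flows with a warning when a matrix is
assembled — the uniform-benchmark denominators of the spatial indices
need a complete matrix, and absence of a recorded corridor is treated as
absence of flow. Lagged predictors reference year−1 within the same dyad;
records whose lag falls outside the panel are dropped from estimation
(logged), never imputed.

## 2. PPML estimation

The conditional mean is multiplicative,
`E[y|x] = exp(alpha_i + gamma_j + delta_t + beta'x)`, estimated by
Poisson pseudo-maximum likelihood: consistent under correct mean
specification whatever the conditional distribution, robust to
heteroskedasticity, and defined at zero flows. Fixed effects are
absorbed by explicit dummy encoding with the first level of each
dimension as reference; at the panel sizes this package targets (up to
tens of thousands of dyad-years and a few hundred coefficients) a dense
solve is faster and simpler than iterative demeaning. IRLS runs to a
relative tolerance of 1e-8 with a cap of 100 iterations; perfectly
collinear columns are detected by pivoted QR (relative pivot threshold
1e-9) and dropped with a warning naming them.

**Clustered covariance.** The multiway cluster-robust estimator is the
inclusion–exclusion sum over all non-empty subsets of the cluster
dimensions, with sign (−1)^(r+1), of one-way sandwich estimators
clustered on the subset intersection. Each one-way sandwich carries the
conventional finite-sample factor G/(G−1)·(n−1)/(n−k) (n/(n−k) in the
unclustered case). The combination can fail positive semidefiniteness —
a known property of the estimator — and is repaired by truncating
negative eigenvalues at zero, with a warning. A dimension with a single
cluster is refused. With three-way clustering and few clusters in one
dimension (e.g. few years) the estimate is conservative and noisy; that
is a property of the estimator, not of this implementation.

**RESET.** The specification test augments the design with the squared
standardised fitted linear predictor (cubic optionally), refits, and
Wald-tests the augmentation with the model's clustered covariance.
Standardising before powering is numerically safer and spans the same
augmentation space given the intercept. In simulation the test holds its
nominal 5% size at the package's reference panel scale (15 locations ×
5 years; empirically ≈0.04–0.05) but over-rejects on very small,
heavily parameterised panels (≈0.09 at 10 locations × 3 years) — a
finite-sample property of generated-regressor tests, worth remembering
before applying RESET to tiny systems.

**Fit statistics.** `squared_correlation` is the squared Pearson
correlation of observed and fitted flows (defined as 0, with a warning,
when either side is constant). `adjusted_pseudo_r2` is McFadden's
1 − (ll − k)/ll₀ against the intercept-only model, with the full Poisson
log-likelihood including the Γ(y+1) continuation so non-integer flows
are handled. The *within* version replaces the null by the
fixed-effects-only fit and penalises only the substantive coefficients —
it answers "what do the theory variables add beyond the margins?".

**Effect sizes.** Two conventions are exposed explicitly because both
are common in applied prose: `exponential`, 100·(exp(β)−1), the exact
percent difference for a 0→1 binary switch in a multiplicative model;
and `elasticity`, β·Δ%, the linear approximation for a Δ% increase of a
log-transformed predictor.

**Fitted intervals.** Confidence bands for fitted flows are built on the
link scale and exponentiated, exp(η ± z·se(η)), with se(η) from the full
clustered coefficient covariance — fixed-effect estimation uncertainty
included. Link-scale construction guarantees positive bounds; the choice
is recorded in the output metadata.

## 3. Ensemble simulation

Each dyad-year receives an independent truncated-normal draw
TN(ŷ, σ²; a, b) with σ = (upper − lower)/(2z) recovered from the fitted
interval at the configured level, a = 0 and b = ∞ by default. No finite
upper bound is imposed because nonnegativity is the only restriction the
method itself requires; any finite default would be an invention, and b
is configurable per run. σ = 0 yields the fitted value clipped to
[a, b]. Sampling is inverse-CDF (`scipy.stats.truncnorm.ppf` on uniforms),
so ensembles are exact deterministic functions of the root seed;
per-(year, draw) substreams come from `SeedSequence` spawn keys, making
results independent of execution order. Draws are independent across
years as well as dyads: no temporal correlation is modelled.

**Row calibration** rescales each origin's simulated outflows
multiplicatively to the observed outflow total of that origin-year.
Scaling preserves within-row proportions and zeros — no corridor can
appear that the model predicted to be empty — and makes every draw's
system total equal the observed total. A zero observed target zeroes the
row; a zero simulated row with a positive target is an error naming the
origin.

**What the envelopes do and do not cover.** Because dyads are drawn
independently, the ensemble represents estimation uncertainty as
independent per-cell noise. Two components of real observed-vs-fitted
discrepancy are therefore *not* fully covered by construction: the
observed system's own sampling noise, and the correlated (whole-surface)
component of one realised estimation error. System-level index envelopes
consequently under-cover somewhat when the observed data are raw counts
with non-negligible sampling noise — in calibration experiments on
correctly specified Poisson panels, per-index-year coverage of the
full-range envelope is roughly one half to nine tenths depending on
scale, while *plug-in* coverage (pseudo-observations drawn from the
simulation process itself) is exactly calibrated (≈95% inside the 95%
quantile envelope). Conclusions should therefore rest on systematic,
directional escapes from the envelope, not on single marginal
index-years; the integration tests use majority-of-years criteria for
this reason.

## 4. Spatial indices

All sums exclude the diagonal. ACV weights each origin's coefficient of
variation of outflows (variance divisor n−1 over the n−1 outflows) by
the origin's share of total flow; origins with zero outflow contribute 0
(their weight is 0 in any case). The Gini index compares every ordered
pair of corridor flows; the default denominator is
(2n(n−1)−1)·Σm — the form used in the migration-index literature this
package follows — with the textbook 2N·Σm (N = n(n−1)) available as
`normalisation="standard"` because the default form does not reach
exactly 1 at maximal concentration. The inequality index is half the
total absolute deviation from the uniform corridor benchmark, as a share
of total flow. Reciprocity reduces each corridor's two directional flows
by min (default), max, or geometric mean and normalises by total flow;
the geometric mean of a corridor with one zero flow contributes 0. The
O(N log N) pairwise-difference identity used for Gini and all other
vectorised paths are tested to 1e-12 against brute-force loops.

## 5. Evaluation

Mahalanobis distances use the ensemble mean and covariance of the
relevant vector (a location's inflow or outflow profile, per year).
With finite S the sample covariance may be ill-conditioned, so it is
shrunk linearly toward its diagonal, Σ* = (1−λ)Σ + λ·diag(Σ), with the
analytic (Schäfer–Strimmer) intensity by default, overridable; λ = 1
reduces D² to the sum of squared componentwise z-scores, and a
pseudo-inverse is the last resort (warned). Distances are reported per
location-year and never aggregated over time. The index envelope is the
full simulated range by default (matching how ensemble outcome ranges
are usually displayed), with quantile envelopes available — quantile
bands are what the calibration experiments use. D² magnitudes are
descriptive; no p-value is attached.

## 6. Synthetic data generator

`generate_panel` draws complete panels from
`flow ~ Poisson(exp(alpha_i + gamma_j + delta_t + beta'x))`. The DGP is
Poisson — not truncated-normal — because the estimation contract is the
Poisson pseudo-likelihood, and known-truth recovery requires generating
from the estimated mean model; the truncated-normal machinery is
exercised downstream on fitted values. Covariates emulate the usual
gravity/network drivers: the log of pairwise distances between random
planar points (symmetric, geography-like), binary symmetric ties with
stated prevalence (contiguity/shared-language analogues), and an
antisymmetric AR(1) log-ratio (relative-size analogue). Defaults: 15
locations × 5 years, intercept 3 (mean corridor flows of a few dozen),
β = (−0.8, +0.5, +0.4), fixed-effect s.d. 0.5/0.5/0.1 — small enough
for sub-second fits, large enough for stable indices. A 31-location ×
20-year profile is available for full-scale bookkeeping.

The generator emulates a *complete, single-source* bilateral panel with
independent Poisson noise. It does not emulate measurement/harmonisation
error in the dependent variable, temporal autocorrelation of flows,
or missing corridors.

**Reciprocity regime.** `generate_reciprocity_regime` produces the
misfit configuration the evaluation machinery is designed to expose:
systems whose corridors are more two-way than any multiplicative model
of their covariates can represent. A fixed-effects PPML constrains every
corridor ratio to m̂_ij/m̂_ji = r_i/r_j — a node-potential structure that
spreads the net imbalance implied by the margins across *all* corridors.
The regime therefore (i) pulls the two directions of each tie corridor
toward balance while preserving the corridor total (weight
w = boost/(1+boost)): genuinely bidirectional exchange on exactly the
corridors whose covariate the model treats symmetrically; and (ii) adds
mean-zero origin-year log shocks (s.d. w·0.8) emulating origin-specific
emigration waves — these cancel from the observed-vs-ensemble comparison
when row calibration is on (calibration transfers observed row totals
into every draw) but inflate the clustered uncertainty, and hence the
envelope width, the way real residual heterogeneity does. A simpler
design — a symmetric dyad-level random effect shared by both directions —
was evaluated first and rejected: reweighting corridors independently of
their balance leaves expected reciprocity essentially unchanged while
inflating concentration, the opposite of the intended signature. At
boost 0 the regime reduces bit-exactly to `generate_panel`; reciprocity
increases monotonically in the boost; and in the integration experiment
(boost 9, S = 200, three-way clustering, calibration on) observed
reciprocity exceeds the simulated envelope in most or all years while
the concentration indices remain covered at their baseline rate.

## 7. Numerical choices and degenerate inputs

- IRLS tolerance 1e-8, max 100 iterations; non-convergence raises with
  the deviance trace.
- Collinearity threshold: pivoted-QR relative pivot 1e-9.
- PSD repair of multiway covariances: eigenvalue truncation at zero,
  warning emitted only when the violation exceeds numerical noise.
- Degenerate correlation (constant fitted or observed) → squared
  correlation 0 with a warning, not NaN.
- All-zero matrices make every index undefined and raise a dedicated
  error rather than returning NaN.
- Row calibration tolerance: row sums match targets to 1e-9 relative.
- Seeds: one root seed; per-(year, draw) `SeedSequence` spawn keys.

## 8. Problem sizes used in the test and acceptance runs

Replicated experiments run at the reference scale of 15 locations ×
5 years: parameter recovery and CI coverage over 200 (tests) / 100
(acceptance script) replications, RESET size over 500 / 300
replications, envelope calibration over 200 pseudo-observations against
a 500-draw reference ensemble, and the misfit experiment at boost 9 with
S = 200. These sizes give Monte-Carlo standard errors comfortably inside
the stated tolerance bands while keeping a full run in the minutes
range on a single CPU.

## 9. Known limitations

- Independent per-dyad draws understate correlated estimation error;
  see §3 for the envelope-coverage consequences. A parametric bootstrap
  of the coefficient vector would cover it, at the cost of departing
  from the independent-dyad simulation contract this package implements.
- Three-way clustered inference with very few clusters in one dimension
  (short panels) is noisy; the RESET combined with it inherits that.
- No temporal dependence in either the generator or the simulator.
- The Gini default normalisation tops out slightly below 1 by
  construction (see §4); comparisons across systems of different size
  should use one fixed normalisation.
- Envelope and distance evaluations condition on the fitted model; they
  do not account for model-selection uncertainty.
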