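# Methods

This note documents the statistical models implemented in `tmakit`, the
assumptions behind them, the defaults and why they were chosen, and what
the synthetic-data generators do and do not emulate.

## Spatial model

Cells on a tissue-microarray (TMA) core are treated as a marked spatial
point pattern: locations in µm inside a disc window, with phenotype
marks (`CD8`, `CAIX`, `other`) and optional tumor/stroma compartment
labels. The association between two phenotypes is summarized by the
cross-type Ripley K function

    K_ij(d) = E[# type-j cells within d of a typical type-i cell] / λ_j,

which equals πd² when the two types are independent homogeneous
processes. The estimator is

    K̂_ij(d) = |W| / (n_i n_j) Σ_(x_i, x_j) e(x_i, x_j) · 1[‖x_i − x_j‖ ≤ d],

summing over ordered (i, j) pairs.

**Edge correction.** Default is the translation correction
e(u, v) = |W| / |W ∩ W_{v−u}|, computed in closed form for disc windows
(lens area of two overlapping discs) and via polygon intersection for
polygonal windows. It is unbiased for stationary processes and valid
for any convex window. `none` (e ≡ 1) is retained both as a fast mode
and as the form that an O(n²) brute-force oracle reproduces exactly.
Raster mask windows (compartment-restricted analyses) support only
`none`; the mask area is the normalizing area.

**Ties and degenerate pairs.** Duplicate coordinates are allowed; a
pair at distance 0 counts toward every d > 0 but not d = 0, so
K̂(0) = 0 and K̂ is non-decreasing. Self-pairs are excluded.

**Symmetry.** Because the pair sum and the translation weights are
symmetric in the two types, K̂_ij ≡ K̂_ji exactly; equivalently
λ̂_i λ̂_j K̂_ij(d) is a symmetric pair statistic.

**Monte Carlo envelopes.** Independence is assessed with pointwise
min/max envelopes over `n_sim` null re-simulations. A min/max band over
n_sim simulations has two-sided pointwise exceedance probability
2/(n_sim + 1) under the null, so the default n_sim = 199 attains the
99% level exactly; the constructor rejects inadmissible (n_sim, level)
pairs. Two null models are provided and recorded in the output
metadata:

* `random_labeling` (default): permutes the type_i/type_j marks over
  their fixed union of locations. It conditions on the observed spatial
  inhomogeneity and tests whether marks are independent of position.
* `csr_j`: fixes the type_i points and re-simulates type_j as CSR with
  the same count. It tests against a homogeneous independent type_j.

The choice matters: a process in which both types are clustered around
*shared* parents has marks that are exchangeable given locations, so
random labeling has, by construction, no power against it — the csr_j
null is the appropriate contrast for co-clustering alternatives, and is
what the direction-recovery tests use for the attraction generator.
For repulsion-by-thinning either null works. Under random labeling the
observed pattern is exchangeable with the simulations, so band coverage
is exact at the nominal level; this is verified empirically in the test
suite and by `scripts/acceptance.py`.

**Evaluability filter.** Sparse cores give unstable envelopes; cores
are kept only when the marked-cell density strictly exceeds a threshold
(default 4×10⁻⁵ cells/µm², combined over the two marked types; a
per-type variant is exposed). Dropped cores are reported with reasons.

**Family-wise envelope.** Per-core envelopes on a common distance grid
are aggregated by taking the per-distance minimum of lower bounds and
maximum of upper bounds. Aggregation refuses mismatched grids rather
than interpolating. Classification of an estimate against a band
labels each distance below/within/above; the scalar summary is the
label of the longest contiguous run inside the distance range of
interest.

**Distance grid.** Default 0–200 µm in 2 µm steps, covering the spatial
scales relevant on a 0.7 mm core (and the 25–160 µm window where
repulsion-like signals are typically reported). Image-convention
coordinates (y down) are accepted as-is: every statistic is
distance-based.

## Core-level association

Core-level counts and densities (overall, tumor, stroma; density =
count / compartment area) feed two analyses:

* **Spearman correlation** with average ranks for ties; exact
  permutation p-value by full enumeration for n ≤ 9, the t
  approximation otherwise. Percentile bootstrap CIs resample cores in
  pairs (B ≥ 200 enforced; degenerate zero-variance resamples are
  redrawn and the redraw count logged).
* **Count regression** for the CD8 count with log link and offset
  log(compartment area): intercept + CAIX density + TMA-slide indicator
  + CAIX×TMA interaction. The offset reconciles modelling a count
  response with a density-scale effect. Families: negative binomial
  (NB2; dispersion θ = 1/α by ML) and zero-inflated Poisson with an
  intercept-only inflation component. Fits are delegated to
  statsmodels behind this interface; optimizer fallbacks (newton →
  bfgs → nm) and a pseudo-inverse covariance handle boundary solutions
  (α → 0 on equidispersed data), which are flagged, never silent.
  CAIX density (cells/µm², numerically ~10⁻⁴) is rescaled ×10⁴
  internally for optimizer conditioning; coefficients are reported on
  the original scale. Model choice is by AIC (−2ℓ + 2k, k counting the
  dispersion/inflation parameter); slide-conditional CAIX effects use
  the Wald variance of β_CAIX (+ β_interaction) from the coefficient
  covariance. TMA slides are coded with the alphabetically first slide
  as reference. Cores are treated as independent units (fixed slide
  effects, no random effects), matching a core-level analysis.

## ssGSEA hypoxia score

The per-sample enrichment score is the weighted running-sum form: rank
genes by expression within the sample (average ranks for ties), walk
the list in descending order, and sum the difference between the
weighted in-set ECDF (weights rank^α, α = 0.75) and the unweighted
out-of-set ECDF. No cross-sample normalization is applied (single-
cohort use). Ties are walked in gene-identifier order, which makes the
score exactly invariant to the row order of the matrix. Gene-set
members absent from the matrix are dropped with a logged count. The
score is rank-based, hence invariant to strictly monotone transforms of
a sample's expression; note that a rank statistic takes finitely many
values, so samples with identical rank vectors tie exactly. With α = 0
the score reduces to the unweighted KS-style running sum. The hypoxia
gene set itself is an input (GMT); the correlation table reports
Spearman ρ and p for log CD8A vs the hypoxia score and vs CAIX (CA9)
expression, with the log transform flag-controlled for matrices already
on log scale.

## Survival analysis

* **Kaplan–Meier** product-limit estimates with Greenwood variance;
  k-sample **log-rank** test from the standard hypergeometric
  observed-minus-expected tally.
* **Tertile categorization** cuts at the 34th/66th percentiles
  (linear-interpolation quantiles): low < p34 ≤ moderate ≤ p66 < high;
  all-equal input collapses to one category with a warning.
* **Cox proportional hazards** by Newton–Raphson with step halving on
  the partial likelihood; Efron tie handling by default (Breslow as an
  option, for parity with software whose default differs), tolerance
  1e-8 on the score, monotone likelihood (separation) detected via a
  standardized-coefficient screen and flagged rather than reported
  silently. Baseline cumulative hazard by the Breslow estimator;
  martingale and deviance residuals per subject (martingale residuals
  sum to 0 at the MLE). Factors (FIGO stage I–IV, grade 1/2/3/NA)
  enter as treatment-coded dummies over observed levels.
* **Leave-one-out influence**: refit without each subject, report per-
  coefficient deltas; a subject is flagged when any |Δβ| exceeds 3
  standard errors (the "unusually sizeable impact" screen,
  operationalized; ranking uses the SE-standardized delta so covariate
  scales do not distort it). Exclusion of a subject is an explicit
  user action, never automatic.
* **Proportional-hazards supremum test**: the observed standardized
  cumulative score process (partial sums of Schoenfeld residuals over
  event times) is compared with multiplier (wild-bootstrap)
  realizations of the per-subject score-residual processes, including
  the I(t)I(∞)⁻¹ correction for the estimation of β, i.e. the
  Lin–Wei–Ying construction behind Kolmogorov-type supremum
  diagnostics. p = fraction of simulated suprema ≥ observed. Empirical
  size at α = 0.05 is verified at ~5% in the test suite.
* **Post-hoc power**: fraction of simulated Weibull-baseline cohorts in
  which the Wald test on the target coefficient rejects; administrative
  censoring fixes the event fraction. A published power figure for a
  real cohort depends on that cohort's covariate distribution and is
  not reproducible from a synthetic stand-in; the tests therefore check
  size under the null, the consistency limit, and monotonicity in n.

## Synthetic data generators

The generators produce every pipeline input with known truth. One
seeded generator per call; independent child streams for
points/marks/masks so added features do not shift existing draws.

* **Cores** (`simulate_core`): disc window of radius 350 µm (a 0.7 mm
  core biopsy); default intensities λ_CD8 = 2×10⁻⁴, λ_CAIX = 4×10⁻⁴,
  λ_other = 10⁻³ cells/µm², chosen so that a 4×10⁻⁵ evaluability
  threshold is meaningful (per-core totals in the tens to hundreds of
  cells). Interactions: `independent` (two homogeneous Poisson
  processes), `attraction` (a fraction `interaction_strength` of each
  type drawn as offspring of *shared* Thomas-process parents, cluster
  sd = interaction_radius, parents simulated on an extended window for
  stationarity), `repulsion` (type_j points within interaction_radius
  of any type_i point deleted with probability interaction_strength).
  The tumor/stroma mask is one smooth random blob per core: a sum of
  six random plane cosines with wavelengths of order the core radius,
  thresholded at the quantile matching the target stroma fraction
  (areal accuracy well within ±0.1). Full-strength repulsion at high
  type_i intensity can thin type_j close to extinction; direction-
  recovery studies use moderate radii for that reason.
* **Cohorts** (`simulate_cohort`): covariates emulate an ovarian-cancer
  cohort (age ~ N(57, 11²); FIGO stage probabilities (0.45, 0.20,
  0.25, 0.10) reflecting frequent early-stage diagnosis; grade
  (0.15, 0.30, 0.40, 0.15) including an NA level; residual disease
  after debulking 30%; family history 25%). CD8 and CAIX densities are
  truncated normals (nonnegative, unimodal; no published distribution
  exists to copy) with means 20 and 50 and sds 15 and 30 on a
  cells/mm²-like scale — the scale on which a *unit* increase is a
  sensible clinical contrast, so the default CD8 log hazard ratio of
  −0.026 per unit (HR 0.974) is the generator's headline truth. The
  published per-unit effect does not state its density unit; per µm²
  it would be astronomically scaled, so this package fixes the unit by
  construction and documents it. Event times follow a Weibull-baseline
  Cox model (shape 1.2, scale 90 months) with covariates centred in
  the linear predictor (absorbed into the baseline; coefficients
  unchanged). Censoring is administrative, uniform on (0, c_max), with
  c_max calibrated by bisection so the expected censored fraction hits
  the target (default 0.5) within ±0.05. True coefficients, the
  calibrated window and degenerate-covariate warnings travel in the
  data frame's `attrs`.
* **Expression** (`simulate_expression`): a latent per-sample hypoxia
  factor h ~ N(0,1); gene-set genes load on h with U(0.5, 1.5)
  loadings plus N(0, noise_sd²) noise; a CAIX-like gene (CA9) loads on
  h directly; the CD8A-like gene is generated at a target *Spearman*
  correlation with h via the Gaussian-copula map ρ_P = 2 sin(πρ_S/6).
  Remaining genes are noise around fixed gene-specific baselines.

**What the generators do not emulate** — and hence what passing tests
do not establish about real data: real tissue morphology (the mask is a
smooth blob, not stroma architecture), segmentation/classification
error in the upstream cell calling, per-core intensity heterogeneity
between patients, informative censoring, platform effects in the
expression matrices, and the actual MSigDB hypoxia signature (the set
is synthetic and supplied as an input). The pipeline's statistical
operating characteristics (coverage, size, unbiasedness, direction
recovery) are what the synthetic studies validate.

## Numerical choices and degenerate inputs

* Envelope admissibility 2/(n_sim+1) ≤ 1−level is enforced, not warned.
* Cross-K requires ≥1 point of each type (error names the empty type);
  distances must be strictly increasing and within the window diameter.
* Zero-variance inputs raise dedicated errors (correlation undefined;
  rank-deficient designs name the aliased columns).
* Cox fits converge to |score|∞ < 1e-8 or are flagged; singular
  information falls back to a pseudo-inverse with a flag.
* All randomized procedures accept a seed or Generator; identical seeds
  give bit-identical outputs (tested).

## Problem sizes in validation runs

The simulation studies in the test suite and acceptance script use 500
replicates × 199 null simulations for envelope coverage, n = 2000
subjects for the Cox recovery, 1000 datasets × 1000 resamples for
bootstrap coverage, 200 replicates for NB recovery and PH-test size,
1000 replicates for log-rank size, and 50 seeds for direction
recovery — sizes at which Monte Carlo error is small relative to the
tolerances asserted.

## Known limitations

* Translation correction is exact for discs/polygons but unavailable
  for raster masks (use correction "none" there).
* The Efron score process in the PH diagnostic uses Breslow-style
  per-time means (standard practice; differences are negligible at the
  tie rates of clinical data).
* The NB/ZIP optimizer can sit at the α → 0 boundary on equidispersed
  data; results are returned with a flag and pseudo-inverse covariance.
* Attraction and repulsion strengths are not calibrated to any real
  tissue; they are levers for validation studies.
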