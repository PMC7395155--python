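# Methods note

This note records the statistical model implemented by `whaledens`, the
assumptions behind it, the default parameter values and why they were
chosen, what the synthetic-data generator does and does not emulate, and
the numerical choices that matter for reproducibility.

## 1. Ship-survey estimator (distance sampling)

### Model

Perpendicular sighting distances x ∈ [0, w] are modelled with a
detection function g(x), g(0) = 1 (detection on the trackline is
certain). Two key functions are provided:

- half-normal: g(x) = exp(−x² / 2σ²)
- hazard-rate: g(x) = 1 − exp(−(x/σ)^(−b))

The scale may depend on sighting-level covariates,
σᵢ = exp(β₀ + Σⱼ βⱼ zᵢⱼ). The likelihood is conditional on detection:

    ℓ(β) = Σᵢ [ log g(xᵢ; σᵢ) − log μᵢ ],   μᵢ = ∫₀ʷ g(x; σᵢ) dx

The average detection probability is P̂ₐ = mean(μᵢ)/w, the effective
strip half-width is ESW = P̂ₐ · w, and density is

    D̂ = n · E[s] / (2 · ESW · L)

with n detected groups, E[s] the sample mean group size and L total
transect length (km). CV(D̂) combines CV components in quadrature:

    CV(D̂)² = CV(n/L)² + CV(ESW)² + CV(E[s])²

SE(P̂ₐ) is propagated from the observed-information covariance of β̂ by
the delta method (numerical Hessian and gradient via
`statsmodels.tools.numdiff`).

Model selection is by AIC across candidate key/covariate combinations;
fits whose Cramér–von Mises test rejects at α = 0.05, or whose
optimiser did not converge, are flagged and excluded from selection.

### Assumptions

- g(0) = 1 (no trackline-avoidance or missed animals at distance zero).
- Distances measured without error; animals do not move responsively
  before detection.
- Detections independent; group size recorded exactly.
- Truncation at w discards the data beyond w (options: none, 5th
  percentile, or a fixed distance in km).

### Goodness of fit

`cvm_test` evaluates the Cramér–von Mises statistic of the distances
against the fitted CDF F̂(x) = ∫₀ˣ g / μ using the asymptotic null
distribution (`scipy.stats.cramervonmises` with a callable CDF). No
correction for parameter estimation is applied, so p-values are exact
only when the distances being tested were not themselves used to fit
the model; testing the training sample is mildly conservative. The test
refuses samples of fewer than 10 distances.

## 2. Satellite FOI scoring

Each feature of interest is rated 0/1/2 against 13 criteria ψ₁…ψ₁₃
(shape, length, colour contrast, fluke-print, blow, etc.). The total is
a weighted sum with default weights (2, 2, 2, 2, 1, 1, 1, 1, 1, 1, 1,
1, 1) — the first four criteria are the primary morphological cues and
carry double weight — so C_s ∈ [0, 34]. Classification thresholds:

| label | rule |
|---|---|
| definite | C_s > 9 |
| probable | 7 ≤ C_s ≤ 9 |
| unclassified | C_s < 7 |

The weight vector and thresholds are configurable
(`SurveyConfig.criterion_weights`, arguments to `classify`).

The class proportion p̂ = k/n over the n scored FOIs carries a binomial
standard error √(p̂(1−p̂)/n); the corresponding count CV is SE(p̂)/p̂.
Raw snapshot density is the class count divided by the imaged area.
The empirical score distribution can be summarised by a
negative-binomial maximum-likelihood fit (`fit_score_distribution`),
with a degenerate flag when all scores are equal. Inter-observer
agreement on a jointly reviewed subset is summarised by the mean and SD
of per-FOI score deviations; a mean absolute deviation ≥ 1 flags a
systematic difference worth adjudicating.

## 3. Surface availability from tag records

### Estimator

Each time–depth deployment contributes daylight seconds above (E_s) and
below (E_d) the surface threshold; T = E_s + E_d. The pooled,
duration-weighted availability is

    â = Σᵢ E_sᵢ / Σᵢ Tᵢ

i.e. a weighted mean of per-tag proportions pᵢ = E_sᵢ/Tᵢ with weights
wᵢ = Tᵢ/ΣT. Two dispersion summaries are reported:

- SE(â) = SD(p) / √m over the m tags (simple between-tag standard
  error of the per-tag proportions);
- CV(â) from the weighted between-tag standard deviation with the
  reliability-weight small-sample correction,

      CV(â) = sqrt( Σ wᵢ (pᵢ − â)² / (1 − Σ wᵢ²) ) / â.

The correction generalises Bessel's n/(n−1) factor to unequal weights;
without it the weighted SD is biased low for small m. For the bundled
21-tag dataset the corrected CV is 0.351 (the uncorrected value is
0.339, and the unweighted SD/mean is 0.379). Between-whale variability
dominates this CV, so it is deliberately not the SE of the mean: when
â divides a density, the relevant uncertainty includes the whale-level
heterogeneity in surfacing behaviour.

### Raw depth series

`summarise_tag` reduces a depth series to (E_s, E_d, T): samples with
depth strictly below the threshold count as surface; non-daylight
samples are excluded; the sampling interval is the per-deployment
median Δt, and gaps longer than 1 s contribute no time. Negative depths
(pressure-sensor drift) are clamped to zero on read.

### Adjustment

The corrected satellite density is d̂_adj = d̂ / â, with

    CV(d̂_adj)² = CV(d̂)² + CV(â)².

### Parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| surface threshold | 1.0 | m | approximate depth to which a humpback body remains visible in imagery of these waters |
| daylight only | yes | — | satellite scenes are acquired in daylight; night behaviour is irrelevant to the snapshot |
| weighting | duration | — | longer deployments estimate their whale's proportion more precisely |

## 4. Reporting

`build_comparison` assembles the four class rows (definite, probable,
unclassified, definite+probable), adjusts each by â, and reports
ship/satellite ratios computed from **unrounded** intermediates; only
display values are rounded. Rounding is round-half-up at the printed
precision (`round_half_up`), matching how the summary tables are
conventionally typeset, rather than banker's rounding. The whole-scene
density denominator is the full imaged area (971 km² for the reference
scene = 635 km² calmer + 336 km² rougher strata by sea state); per-class
counts are not re-stratified unless requested because the definite and
probable counts are too small to split stably.

## 5. Synthetic-data generator

### What it emulates

- **Population**: homogeneous spatial Poisson process of groups over the
  scene; zero-truncated Poisson group sizes with the rate solved
  (Brent's method) so the truncated mean equals the configured 2.06.
- **Dive behaviour**: alternating exponential surface and dive bouts
  (means 60 s and 117 s → long-run surface fraction 60/177 ≈ 0.339);
  surface depths U(0, 0.8) m, dive depths U(5, 40) m, sampled at a
  configurable rate (10 Hz default).
- **Ship survey**: a mid-scene transect; detection is Bernoulli
  thinning by g(distance) × instantaneous availability with a
  half-normal g (σ = 1.5 km, w = 6 km by default).
- **Satellite FOIs**: each individual is snapshot-available with
  probability equal to the surface fraction; available whales emit
  criterion ratings from per-criterion emission tables (primary
  criteria (0.48, 0.42, 0.10) weighted / secondary (0.40, 0.52, 0.08)
  unweighted over ratings (2, 1, 0)); sea state downgrades ratings with
  stratum-dependent probability (0 ideal … 0.50 poor); non-whale
  clutter arrives as a Poisson process at 0.42 features·km⁻² with a
  clutter emission table (0.86, 0.11, 0.03). The emission defaults were
  tuned once, before any test thresholds were set, so the long-run
  definite:probable:unclassified split is near the reference 18:21:146
  proportions; a single shared emission table cannot reproduce that
  split exactly because the probable band [7, 9] is narrow relative to
  the score SD, so simulated probable fractions sit within about one
  percentage point of the target.
- `perfect=True` disables clutter and emits all-2 scores, isolating the
  availability thinning for identity tests.

### What it does not emulate

- Spatial clustering or density gradients (the Poisson field is
  homogeneous); responsive movement; detection-distance measurement
  error; duplicate detections between platforms; observer-specific
  scoring behaviour; diel or seasonal changes in dive cycles;
  correlation between sea state and whale behaviour. Surface/dive bouts
  are memoryless, so surfacing-bout autocorrelation in real tag records
  is absent.

## 6. Numerical choices

- Half-normal μ = ∫₀ʷ g has the closed form σ√(π/2)·erf(w/σ√2);
  hazard-rate μ uses 61-node Gauss–Legendre quadrature, ample for the
  smooth integrand on [0, w].
- Detection fits run L-BFGS-B from multiple starting points; the
  covariate-free half-normal MLE is then polished by solving the
  analytic score equation with `brentq` (xtol 1e-14), driving
  |∂ℓ/∂σ| below 1e-6; hazard-rate fits are polished by Nelder–Mead.
- The reliability-weight CV uses exact weight algebra, no resampling.
- Simulation-based tests in the suite use replicate counts (100–300)
  and sample sizes (n ≈ 200–2000) chosen so Monte-Carlo error is small
  relative to the tested tolerances (typically 3 SE or 5% relative),
  while keeping the full suite around a minute of runtime.
- All simulation entry points accept a `numpy` Generator or seed;
  identical seeds give byte-identical outputs.

## 7. Limitations

- The ship-side CV treats encounter-rate, detection and group-size
  components as independent; any covariance between them is ignored.
- The availability correction assumes tagged whales are representative
  of whales in the imaged scene, and that the 1 m threshold matches
  what an image analyst can actually see — misspecifying either shifts
  adjusted densities multiplicatively.
- The binomial class SE conditions on the total FOI count; it does not
  capture scene-to-scene variation in clutter or missed FOIs.
- The Cramér–von Mises p-value is asymptotic and, when applied to the
  training sample, conservative.
- Negative-binomial score fitting is a descriptive summary; criterion
  scores are bounded (0–34) and the NB support is not.
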