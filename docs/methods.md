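# Methods

`pestmap` implements a surveillance-analysis pipeline for areal counts of
urban pest complaints: seasonal trend regression on monthly series,
indirect standardization to standardized incidence ratios (SIR), and a
Bayesian hierarchical spatiotemporal Poisson model with space–time
interaction variants compared by DIC. This note records the models, the
numerical choices, and what the synthetic generator does and does not
emulate.

## Harmonic trend model

Monthly complaint counts show strong annual seasonality (late-summer
peaks) superimposed on a secular trend whose seasonal swing itself changes
over the years. We model a monthly series `y_t`, `t = 0, …, T−1`, as

    y_t = β0 + β1 t + (a + b t) cos(2π t / 12 − ψ) + ε_t,

a harmonic with period fixed at 12 months whose amplitude varies linearly
in time. The model is linearized in the standard way to six OLS columns

    [1, t, sin(ωt), cos(ωt), t·sin(ωt), t·cos(ωt)],   ω = 2π/12,

so that the instantaneous seasonal amplitude
`A(t) = sqrt((β2+β4 t)² + (β3+β5 t)²)` is a derived quantity rather than a
constraint — rising and falling seasonal signals fit the same model. The
fit uses an orthogonal (SVD) decomposition, not normal-equation inversion;
the test suite holds it to an extended-precision normal-equation oracle at
1e-8.

Decisions and conventions:

- `t` starts at 0 at the first month and is left uncentered; this affects
  only the interpretation of `β0` (level at the first month).
- When a denominator series accompanies the counts (total inquiries, or
  population), the response is standardized to `100·y/denominator`
  (a percentage) before fitting. Both raw-count and standardized entry
  points exist because either convention is defensible for a citywide
  series; per-subregion fits should standardize by population.
- The secular-trend test is the two-sided t-test on `β1` with `n − 6`
  degrees of freedom. Whether a "declining trend" should instead be read
  as the joint decline of the amplitude terms is ambiguous, so the joint
  Wald F-test on `(β4, β5)` is reported alongside, and `classify_trend`
  uses `β1` only.
- For a zero-variance response, `R²` is defined as 0.
- Plain linear-model inference throughout; no autocorrelation-robust
  (Newey–West) standard errors. This is a documented limitation: monthly
  complaint residuals are mildly autocorrelated in practice and the
  nominal trend p-values are anti-conservative to that extent.
- Single fixed period of 12 months; no harmonic-order selection.

The per-area concordance regression between two reporting streams
(e.g. building-owner infestation reports vs resident complaints) is a
simple OLS of one count vector on the other with intercept; the 95% CI
uses t quantiles with `n − 2` degrees of freedom. It refuses fewer than
three areas or a zero-variance regressor.

## Indirect standardization

For observed counts `y_it` with populations `n_it`, the expected count is
`E_it = r n_it` with reference rate `r = Σ y / Σ n` computed within a
standardization stratum. The default stratum is the period (year): SIR
maps are usually drawn per year, and per-period standardization makes
`Σ_i E_it = Σ_i y_it` hold exactly within every period. A pooled mode
(single `r` for the whole panel) is provided for sensitivity. The SIR is
`y/E`; zero observed counts give SIR 0, which is valid. Zero or negative
populations are rejected at panel construction rather than dropped
silently — administrative geographies should never have them — and a
pre-filter (`drop_unpopulated`) is provided for dirty real-data extracts.
A crude `rate_per_100k` export is also provided, since choropleth displays
often use the per-capita rate rather than the SIR.

Note that per-period standardization absorbs the panel-wide level and the
common temporal profile into `E`. When the spatiotemporal model is fit to
a panel standardized this way, its intercept and temporal effects describe
departures that standardization left behind; when fit to a panel with a
fixed generative offset (as in the recovery studies below), the intercept
is the region-wide log level itself.

## Spatiotemporal model

Counts per area `i` and period `t` (years, for this model; the monthly
resolution lives entirely in the harmonic analysis):

    y_it ~ Poisson(E_it exp(η_it)),
    η_it = b0 + u_i + v_i + γ_t + φ_t + δ_it.

- `u`: spatially structured ICAR field; precision matrix τ_u·Q_u with
  `Q_u = D − W` the contiguity-graph Laplacian; generalized rank
  `n − n_components`, sum-to-zero per connected component (disconnected
  geographies — an island borough — are supported).
- `v`: exchangeable Gaussian ("IID") spatial field. `u + v` is the
  classic BYM convolution, not the scaled reparameterization.
- `γ`: RW2 (second-difference penalty) temporal field; rank `T − 2`; null
  space {constant, linear}.
- `φ`: IID temporal field.
- `δ`: space–time interaction with Knorr-Held-type structure —
  type I: IID⊗IID (rank `nT`); type II: RW2-in-time within each area
  (rank `n(T−2)`); type III: ICAR-in-space within each period
  (rank `T(n − n_components)`). `δ` is stored area-major, so type II is
  `I_n ⊗ Q_rw2` and type III is `Q_u ⊗ I_T`.
- Flat prior on `b0`; Gamma(1, 5e-4) hyperprior on every precision — a
  conventional weakly-informative disease-mapping default, overridable in
  the model spec; the test suite includes a Gamma(0.5, 5e-4) sensitivity
  fit.

### Sampler

Metropolis-within-Gibbs:

- Precisions: conjugate Gamma updates
  `τ | x ~ Gamma(a + rank(Q)/2, b + xᵀQx/2)`, with the *generalized rank*
  (not the dimension) as the exponent for intrinsic fields.
- Latent fields and `b0`: adaptive random-walk Metropolis. Sites that are
  conditionally independent given the rest — same-color nodes of a greedy
  coloring of the contiguity graph for ICAR fields, `t mod 3` classes for
  RW2 fields (bandwidth 2), everything at once for IID fields and for the
  type-I interaction — are proposed and accepted in a single vectorized
  step. One step size per block, tuned toward 30–50% acceptance every
  `adapt_window` sweeps during burn-in only, so the post-burn-in chain is
  a fixed Markov kernel.
- Constraints by post-sweep re-centering ("centering on the fly"): the
  intrinsic fields' null-space components are removed after every sweep
  and absorbed into the model term they are confounded with, leaving η
  exactly invariant — per-component means of `u` into `v`, the mean of
  `v` into `b0`, the mean of `γ` into `b0` and its linear part into `φ`,
  the mean of `φ` into `b0`, per-area means of a type-II `δ` into `v`,
  per-period means of a type-III `δ` into `φ`. Null-space directions that
  are *not* confounded with any other term (e.g. the per-area linear
  components of a type-II `δ`) are identified by the likelihood and left
  alone. Pre-centering constraint residuals are logged per retained draw.
  Re-centering of this kind is the standard implementation of constrained
  intrinsic fields in Gibbs samplers; it is approximate relative to exact
  constrained sampling, which is why constraint residuals are exposed.
- Initialization warm-starts from the saturated log-rate surface
  `log((y+0.5)/E)` split into its row/column means, which avoids the slow
  escape from a zero-field, high-precision initial state.
- Divergence guard: |η| > 50 aborts with the offending cell and a state
  dump; a non-finite posterior at initialization is an error.
- Reproducibility: one `numpy` Generator seeded from the spec; multiple
  chains use independent seeds (`seed + 1009·chain`), never shared
  streams; fixed seed gives bit-identical output. With ≥ 2 chains a
  split-chain potential-scale-reduction diagnostic is reported for `b0`.
- Prior-only mode (the likelihood ignored) returns exact ancestral draws
  from the joint prior — precisions from their Gamma hyperpriors, fields
  from the corresponding constrained GMRFs — rather than a Markov chain.

### DIC and relative risk

`D(η) = −2 Σ log Poisson(y | E e^η)` including the `log y!` constant;
`d̄` is the mean over retained draws, and the plug-in deviance is
evaluated at the posterior mean of **η** (not of the components
separately) — `p_D` depends on this parameterization choice, so it is
fixed and documented. `DIC = d̄ + p_D`. Negative `p_D` triggers a warning
rather than an error. Model comparison fits each candidate, ranks by DIC
ascending, flags near-ties (|ΔDIC| < 1) and resolves them toward the
smaller `p_D`; a failed fit is recorded and the comparison proceeds with
the survivors.

Relative-risk surfaces are exported in two modes, because "the posterior
mean of the space–time interaction" and "the full area–period risk" are
both defensible readings of what a RR map shows: mode `interaction` is
the posterior mean of `exp(δ_it)` (requires an interaction term); mode
`full` is the posterior mean of `exp(η_it − b0)`. Means of exponentials,
not exponentials of means (Jensen's inequality makes these differ; a test
asserts the direction).

## Synthetic-data generator

The generator produces the structure every downstream stage assumes, so
the pipeline is testable without administrative downloads:

- Lattice: `n_components` disconnected `rows × cols` rook-contiguity
  grids (rook, not queen, for hand-verifiable degree structure; the
  real-geometry reader uses queen contiguity as is conventional for
  irregular administrative polygons). Populations uniform on
  `population_range`, default 20,000–120,000 persons — the scale of
  census-aggregated city neighborhoods.
- Latent fields drawn exactly from their (constrained) GMRF priors via
  eigendecomposition of the structure matrix with null-space coefficients
  set to zero — exact and affordable up to a few hundred areas. The IID
  fields are also centered, so the generative `b0` is the identified
  region-wide level under the same constraint parameterization the
  sampler targets. Note that intrinsic-field precisions are *not*
  marginal-variance reciprocals: an RW2 marginal variance grows like
  `T³/τ`, so the default τ's (10 for spatial, 50 for temporal and
  interaction fields) are chosen to give realized log-risk standard
  deviations around 0.1–0.3 at the panel sizes used here, the range
  typical of disease-mapping applications.
- Panel: `E_it = base_rate · population_i` (default 2e-3 events per
  person-period) and `y_it ~ Poisson(E e^η)`, with an overflow guard that
  names the offending cell. `η` is recorded exactly as the sum of its
  components for conservation tests.
- Monthly series: the harmonic mean structure above with Gaussian noise.
  The noise family of real complaint series is not identified by the
  source material; Gaussian noise around the harmonic mean is this
  package's choice for the series generator, while the panel generator is
  Poisson as the spatiotemporal model requires. A seasonal amplitude that
  would cross zero inside the series (a phase flip) is refused unless
  explicitly allowed by a flag.

What the generator does **not** emulate: 311-style free-text descriptor
vocabularies, reporting-behavior covariates, sociodemographic structure,
population change over time, or overdispersion beyond what the latent
fields induce. Passing tests therefore demonstrate correctness of the
machinery and calibration under the stated generative model, not fidelity
to any particular city's administrative data.

## Study sizes used in the checks

Chosen as desk-scale defaults that keep every property identifiable:

- Interval coverage of `b0`: 20 replicates of a 6×6 grid, T = 24, default
  precisions, chains of 1,500 sweeps (500 burn-in).
- Selection consistency: 10 replicates of a 6×6 grid, T = 10 under a
  strong type-I interaction (τ_δ = 2, field sd ≈ 0.7) with populations
  2,000–12,000 so per-cell expected counts are moderate (≈ 4–24). At that
  count strength the interaction prior's structure matters for the fit,
  which is what separates the candidates' DIC; with very large counts all
  three interaction models fit a nearly saturated surface and their DICs
  genuinely coincide.
- Calibration of the trend test: 500 replicates of a 72-month null
  series.
- GMRF empirical-covariance check: 20,000 draws on a 3×3 grid against the
  Moore–Penrose pseudo-inverse.

## Known limitations

- Single-site random-walk Metropolis mixes adequately at desk scale but
  would need blocking or gradient-based updates for panels with thousands
  of areas.
- DIC has a Monte-Carlo standard error of a few units at the chain
  lengths used here; comparisons closer than that are flagged as ties
  rather than resolved.
- The trend test's nominal level assumes independent Gaussian errors.
- Real-data mode (CSV dialects, GeoJSON queen contiguity) is exercised on
  synthetic fixtures only.
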