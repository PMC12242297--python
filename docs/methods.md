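# Methods

## Observation model

A specimen's response `Y` is one of: a single amino-acid δ¹⁵N (`d15N_Phe`,
`d15N_Lys`), bulk collagen (`d15N_coll`), or a trophic-minus-source
difference (`D15N_Glx_Phe`, `D15N_Glx_Lys`, `D15N_Pro_Phe`,
`D15N_Pro_Lys`). Differences carry a machine sd equal to the quadrature
sum of their constituents' replicate/analytical sds. Each response is
modelled independently (one fit per response; no joint multivariate
model).

    Y_i = s(t_i) + β₁ Z_i + η_i + ε_i,   ε_i ~ N(0, σ²)

* `η_i` — known per-observation machine sd, entering the likelihood
  variance additively (`η_i² + σ²`). It is identifiable alongside σ
  because it is fixed from replicate/standard propagation, not estimated.
* `Z_i` — latent true fish size, prior `N(x̄_i, σ²_{x,i})` from the
  osteometric regression or the size-class prior. Sizes are centred and
  scaled by the sample mean/sd of the prior means before entering the
  model; β₁ is reported both per mm and per size-sd.
* `t_i` — latent true date, uniform on the dating window `[t0_i, t1_i]`
  (calendar years CE, BCE negative, closed intervals).

### Smooth trend (P-spline)

`s(t)` is a clamped cubic B-spline basis of `k` functions (default 10)
on evenly spaced knots over the observed time span, with a second-order
difference penalty `D'D` on the coefficients. The Bayesian form puts
`b ~ N(0, τ² (D'D)⁻)` on the penalized directions; the penalty null
space (constant + linear coefficient sequences) and all coefficients
additionally receive a proper wide ridge (scale 25 ‰) so the prior is
proper. τ (the random-walk scale of the spline increments: small = 
smooth, large = wiggly) gets a half-normal prior (scale 5 ‰).

Estimating the latent dates jointly with the smoothing hyperparameters
is what makes the spline coefficients non-conjugate, so for the smooth
model the dates are *fixed* by an imputation strategy (window midpoint
by default). `sensitivity_over_time_imputations` then refits under
midpoint, both window edges, and m random per-window draws (default 5),
and raises a divergence flag when any two posterior mean curves separate
by more than the pooled pointwise 95% credible half-width — the
operational check that dating uncertainty is not driving the trend.

### Linear trend, fully latent dates

Where a trend segment is near-linear, `s(t) = α + β₀ t` and the latent
dates are retained: the uniform-window integral of the Gaussian
likelihood is a closed-form difference of normal CDFs. The per-specimen
date posterior (a truncated normal on the window, exact conditional on
the hyperparameters) is summarized by `refine_dating`; the sharpening
ratio divides the posterior sd by the prior sd `(t1−t0)/√12`.

## Posterior computation

All latent quantities are marginalized analytically — sizes into the
observation variance (`η² + σ² + β₁²σ_x²`), dates via the CDF
difference, spline coefficients via the Gaussian integral (Woodbury /
matrix-determinant identities, O(n·k²) per evaluation). The remaining
hyperparameters (GAM: α, β₁, log σ, log τ; linear: α, β₀, β₁, log σ)
are sampled with emcee's affine-invariant ensemble sampler,
`chains` (default 4) independent ensembles of 16 walkers, 500 warmup +
500 retained steps each, thinned over steps (keeping whole ensembles at
each retained step) to ~2000 total draws. R̂ and ESS are computed across
the independent ensembles with ArviZ; a fit whose diagnostics miss the
configured thresholds (R̂ ≤ 1.01, ESS ≥ 400 by default) returns with a
prominent `diagnostics_failed` flag and a logged warning — never
silently. Identical seeds and data give identical draws.

Exact conditional draws of the spline coefficients
(`N(M⁻¹B'W r, M⁻¹)`), latent dates (truncated normal via inverse-CDF;
windows where `|β₀|·width` is below 10⁻⁶ of the residual scale fall back
to the uniform prior, whose density the likelihood cannot distinguish at
that point) and latent sizes (conjugate normal) are then reconstructed
per retained draw, so the joint posterior matches full MCMC over all
latents without its dimensionality.

Numerical notes: log-CDF differences are evaluated in whichever normal
tail is better conditioned; the marginal covariance uses a Cholesky of
the k×k inner matrix; degenerate inputs (zero time span, all-missing
sizes, < 10 usable records, empty prediction grids) raise with the
offending field named.

## Trophic position

`TP = (Y − 2.9)/TEF + 1` with `TEF ~ N(6.6, 1.7)` truncated at zero, one
TEF draw per posterior draw; the transform refuses pure source or bulk
responses. The 2.9 ‰ primary-producer offset and the TEF prior are
configurable. A caution for moment summaries: because the truncated
prior retains (vanishingly little, ~10⁻⁵) mass arbitrarily close to
zero enrichment, E[1/TEF] — and hence the exact mean TP — diverges
logarithmically; quantile summaries are unaffected, and the tests
compare Monte-Carlo means against the expectation conditioned on
TEF ≥ 0.1 ‰, which virtually every draw satisfies.

## Osteometrics

Total length is regressed on linear + quadratic terms of each bone
measurement (no cross terms, no stepwise selection) by OLS; residual sd
uses the n − p denominator, and prediction sd combines residual and
coefficient-covariance variance in quadrature. Size-class labels
"lo−hi mm" map to `N(midpoint, range/4)` so the class spans ±2 sd
(~95.4% of prior mass inside the class). Measured ETL takes precedence;
the class prior is the fallback.

## QC and calibration

* C:N acceptance is the closed interval [3.0, 3.6].
* Per-batch calibration is ordinary (unweighted) least squares of true
  on raw standard values; standard raw sds are carried into corrected
  values (scaled by |slope|, plus curve residual sd in quadrature), not
  into the fit.
* The mass-balance bulk estimate is the nitrogen-fraction-weighted mean
  of the measured amino-acid values, with fractions renormalized over
  the AAs present so partial coverage (the 13 measured AAs carry 0.807
  of collagen N) stays unbiased.
* The estimated-vs-observed filter excludes records whose offset lies
  more than 2 *sample* standard deviations from the mean offset,
  computed once, no iterative re-trimming. Under pure normal offsets
  this excludes ~4.6% of records.

## Synthetic assemblages

The generator emulates: a true trophic-offset trend over time (constant,
linear, or Gaussian bump — all closed-form for recovery tests), an
ontogenetic size effect (trophic level per mm), a source-AA baseline,
13-AA profiles in which trophic AAs enrich per trophic level (Glx by
exactly the TEF, Hyp coupled to Pro), source AAs track the baseline and
Thr depletes, independent per-AA machine noise, a per-specimen residual
applied at the trophic-offset level (matching the additive ε of the
model), exact mass-balance bulk values, uniform dating windows
constructed so the true date is uniform within its window, and noisy
normal size priors.

Defaults are the study conditions: 150 specimens over 500–2000 CE,
±100-year windows, lengths 700 ± 150 mm with 30 mm size-prior sd
(typical osteometric regression error), TEF 6.6 ‰, baseline δ¹⁵N_Phe
7 ‰ (a plausible shelf-sea value), machine and residual sds 0.5 ‰
(GC-C-IRMS replicate precision), Gly carrying 30% of collagen N and the
13 AAs 0.807 in total. Within-specimen AA measurement errors are
assumed independent (their true covariance is unknown).

What the generator does *not* emulate — diagenesis and contamination
chemistry, radiocarbon likelihoods (windows are uniform by assumption),
baseline spatial structure, non-Gaussian size errors, and collagen
turnover time-averaging — bounds what passing recovery tests show about
real assemblages: they validate the estimator under the model's own
assumptions, not those assumptions themselves.

## Test problem sizes

Calibration tests use 20 replicate syntheses of n = 150 with reduced
sampler settings (2 ensembles, 400 + 400 steps) — enough for ~1000
effective draws of a 4-parameter posterior; the no-error spline limit
uses n = 500 and checks the posterior mean curve against a direct
generalized-ridge solve at the posterior-median hyperparameters (RMS
agreement < 0.05 ‰); interval-coverage checks use the binomial ≥ 17/20
criterion appropriate to 95% intervals at 20 replicates.

## Known limitations

* Spline-model dates are imputed, not sampled; the sensitivity routine
  detects, but does not repair, imputation-driven divergence.
* β₁ is re-estimated per response, never shared across responses.
* The linear-model CDF-difference likelihood loses precision when the
  window is many residual sds wide *and* the slope is extreme — far
  outside the fitted region in practice.
* One calibration curve per batch is fitted without errors-in-variables
  treatment of the standards' raw sds.
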