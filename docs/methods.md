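# Methods

## The model

`sociomort` fits district-level crude death rates (deaths per 1,000
residents per census year) with a set of three Bayesian linear state-space
regressions that differ only in whether and how neighboring districts'
socioeconomic conditions enter the mean:

* **Baseline** — each district's rate depends only on its own covariates:
  `y_t = X_t β_t + σ_t u_t`, with `X_t` the N×(p+1) design matrix for census
  year `t` (intercept column plus per-year z-scored covariates) and
  `u_t ~ N(0, I_N)`.
* **SP** — adds a spatially lagged term `F_t γ_t`, where row `i` of the N×p
  matrix `F_t` is the unweighted mean of each covariate over district `i`'s
  graph neighbors (districts sharing a border, road or bridge).
* **WSP** — same, but the average runs over *all* reachable districts with
  weights `w_ij = exp(−(d_ij − 1))`, `d_ij` the hop distance on the binary
  graph, row-normalized so the term stays an average. Immediate neighbors
  get weight 1 and the weight decays by a factor `e` per extra hop.

Coefficients are time-varying. Both coefficient vectors follow biased
Gaussian random walks across census years,

    β_t = β_{t−1} + μ_β + L_β v_t,   v_t ~ N(0, I),

with `Σ_β = L_β L_βᵀ = diag(s) C diag(s)`, `s ~ LogNormal(0,1)` elementwise
and `C ~ LKJ(1)` (uniform over correlation matrices; its log-density is
implemented as 0 on valid matrices — the omitted normalizer shifts every
log joint equally and cancels in inference). Drifts are standard normal.
The observation scale follows its own walk on the log scale,
`log σ_t = log σ_{t−1} + μ_σ + ℓ w_t`, `ℓ ~ LogNormal(0,1)`. Index 0 of
every walk is a pre-sample initial condition (`β_0 ~ N(0, Σ_β)`,
`log σ_0 ~ N(0, ℓ²)`); observations use indices 1..T aligned to the census
years in order. The spatial coefficient block (γ, its drift, scales and
correlation) mirrors the β block with dimension p instead of p+1 — the
spatial term carries no intercept.

The innovation vectors `v_t` are (p+1)-dimensional coefficient shocks,
while the observation noise `u_t` is N-dimensional — the only reading under
which the observation equation type-checks.

## Inference

The posterior is approximated by a multivariate normal guide over a flat
unconstrained latent vector, with covariance `FFᵀ + diag(c²)` (low-rank
factors plus diagonal; rank defaults to the full latent dimension and can
be lowered). Latents enter the unconstrained vector in *centered* form:

* coefficient and log-volatility paths as their values (conditionally
  Gaussian given hyperparameters, which suits a Gaussian guide; a
  non-centered/innovation parameterization was tried first and produced the
  classic funnel geometry that a Gaussian guide cannot follow),
* positive scalars (`s`, `ℓ`) through `log`,
* correlation matrices through canonical partial correlations: `tanh` of
  the unconstrained coordinates fills the strict lower triangle, and the
  Cholesky factor is assembled row-wise. The transform's log-Jacobian has
  the closed form `Σ log(1−z²) + Σ log W_ij + Σ_j (K−1−j) log L_jj` and is
  verified against finite-difference Jacobian determinants in the tests.

The ELBO is estimated as the Monte-Carlo mean of the unconstrained-space
log joint at reparameterized draws plus the *closed-form* entropy of the
guide (matrix-determinant lemma on the low-rank covariance). This equals
the usual `E_q[log p − log q]` in expectation with lower variance. The
unconstrained log joint itself is checked against
`log_prior(constrain(z)) + log_likelihood + log_jacobian(z)` to 1e-8.

Gradients come from a small reverse-mode automatic-differentiation core
written for this package (numpy arrays, ~20 operations including batched
matrix products, a linear solve with adjoint-solve gradients, and a
log-determinant primitive); every operation is tested against finite
differences.

### Optimization

Adam with an exponentially decaying step size, 0.02 → 5·10⁻⁴ over the
iteration budget (default 10,000 iterations; early stop when the windowed
mean ELBO gain over 500 iterations falls below 1e-4), 8 Monte-Carlo draws
per gradient (draws are batched, so more draws are nearly free), global
gradient-norm clipping at 100, guide initialized at zero location with
diagonal 0.1. The decay schedule matters: constant-step Adam's stationary
noise biases this hierarchical posterior toward a flat, overdispersed
region in which the noise scale absorbs the guide's own coefficient
uncertainty (σ settles ~2.4× too high); decaying the step recovers the
correct basin. Draws at which the log joint is non-finite are dropped from
the ELBO estimate with a warning (all-dropped is an error), and tanh in
the correlation transform is clamped to keep Cholesky factors nonsingular
in floating point. A single seed drives initialization noise, ELBO
sampling and posterior draws through named substreams.

## Evaluation

Predictions `Ŷ` are noiseless linear predictors per posterior draw (1,000
draws by default, configurable); observation noise can be added with a
flag. Per year, `e_t = (1/N) Σ_i |Ŷ_it − Y_it|` is computed per draw and
averaged over draws. Signed deviations `Ŷ − Y` diagnose systematic bias: a
centered Q% credible interval (empirical quantiles leaving (1−Q/100)/2 in
each tail; Q = 80 by default) entirely above zero flags overestimation,
entirely below zero underestimation. The same machinery summarizes the
coefficient posteriors. The full evaluation grid crosses the 3 model
variants with 3 nested predictor categories (base: 7 deprivation-style
covariates; wealth: +4 wealth covariates = 11; all: +5 age/ethnicity
covariates = 16) and reports the per-year MAE table plus a per-district
breakdown for the final year. Ego-network reports list, for each district,
its neighbors' across-district standardized mortality and standardized
signed error, localizing where the model over- or under-shoots.

## Synthetic data

The generator emulates the structure of the study setting — 18 districts,
three census snapshots (2006/2011/2016), 16 covariates, a sparse connected
road-adjacency graph — without matching any real marginal distribution.

* **Graph.** The bundled 18-district edge list is reconstructed from public
  Hong Kong district geography (borders, tunnels, bridges; 29 edges; Wan
  Chai has four neighbors). It is an editable fixture, not ground truth.
  Chain, grid and random-geometric alternatives support scaling studies.
* **Covariates.** Each feature has a family: log-normal (densities,
  incomes) or logit-normal (proportions, rates), applied to a latent
  Gaussian field with AR(1) persistence ρ = 0.6 across census years and
  mild spatial autocorrelation (each district mixed with its neighbor mean,
  weight 0.3). Location/spread parameters give plausible magnitudes
  (incomes in the tens of thousands, unemployment a few percent).
* **Response.** Generated from the model's own forward equations at a
  stored ground-truth latent state. The default truth has intercept 0.5,
  direct effects 1.0 and 0.8 on two deprivation covariates, a spatial
  effect 2.5 on one covariate, constant coefficients over time, and noise
  σ = 0.5. The spatial coefficient is larger than the direct ones because
  neighbor averaging shrinks its regressor's spread (sd ≈ 0.4 for binary
  neighbor means on the 18-district graph, ≈ 0.18 for the weighted
  version); 2.5 makes the spatial term's contribution comparable to the
  direct effects, i.e. genuinely strong. The model-scale response is
  mapped into a plausible per-1,000 crude-rate range by a recorded affine
  map (offset 5.5, scale 1); recovery tests invert the map, because fitting
  the shifted scale directly puts the intercept in the tail of the
  zero-centered prior and inflates the noise posterior — a prior-data
  conflict any user of these models on real rates should expect.
* **Files.** Fixture CSVs store integer populations and death counts, so
  reloaded rates differ from the exact simulated rates by count rounding
  (< 0.002 per 1,000); exact rates and the truth state live in the
  accompanying JSON.

What passing tests show — and what they do not: the synthetic covariates
are exogenous, complete, and exactly follow the model's assumed families;
real census covariates are none of these. Recovery and calibration results
certify the inference machinery, not the adequacy of the linear-Gaussian
model for real mortality data.

## Verification suite and problem sizes

`scripts/acceptance.py` recomputes, from scratch at run time: the density
oracle (100 random small instances, p ≤ 3, N ≤ 5, T ≤ 3, against an
independently coded per-term sum); the conjugate normal-mean oracle
(posterior mean/sd and log evidence in closed form); the spatial-operator
oracle (exhaustive over all valid graphs with ≤ 5 nodes plus 300 random
6-node graphs, against brute-force loops); credible-interval coverage of
generating coefficients (20 replicate panels at the default study
conditions, 4,000 iterations per fit, 400 posterior draws); spatial-effect
recall (10 replicate sp/wsp fits at 10,000 iterations; a replicate counts
as a hit when the truly nonzero spatial coefficient is flagged in at least
one census year); null calibration (6 replicate null panels, flag rate over
126 non-intercept coefficient intervals); and the structural facts of the
design (7/11/16 predictor categories, 18 districts, 3 years, 3×3
evaluation grid). These replicate counts and iteration budgets are the
package's chosen simulation sizes; they give the statistical checks
binomial error bars of a few percentage points.

## Known limitations

* VI underdisperses: observed 80% CI coverage sits near 74%, within the
  accepted [65%, 95%] band but below nominal — typical for Gaussian guides
  on hierarchical posteriors.
* The LKJ(1) density omits its normalization constant, so reported log
  priors are comparable across states but are not normalized densities.
* With 18 districts and 3 years the spatial variants are weakly identified
  when own- and neighbor-covariates are collinear; the weighted (WSP)
  regressor especially has small spread, and its coefficients need strong
  signals to separate from zero.
* The forward generator holds ground-truth coefficients constant over
  time; time-varying recovery is exercised only through the priors.
* Ego-network reports standardize within a single year across districts;
  with N = 18 these z-scores are noisy descriptive statistics, not tests.
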