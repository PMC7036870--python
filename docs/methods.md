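# Methods

## Problem and notation

A binary health indicator $Y_{ik}$ is observed for sampled individuals
$i$ in small areas $k = 1, \dots, K$ with known population sizes $N_k$.
The target is the true prevalence per area,
$P_k = N_k^{-1} \sum_i Y_{ik}$.  Surveys designed for national or
regional estimates typically leave many areas with tiny samples or none
at all; areas with $n_k = 0$ are *off-sample* and admit no direct
estimate.  Design weights $w_{ik}$ (proportional to inverse inclusion
probabilities) accompany every record and are normalized within area to
sum to $n_k$:
$\tilde w_{ik} = n_k w_{ik} / \sum_{i \in s_k} w_{ik}$.

## Design-based estimators

* Unweighted: $\hat p_k^{UNW} = y_k / n_k$.
* Horvitz–Thompson (Hájek form):
  $\hat p_k^{HT} = n_k^{-1} \sum_{i \in s_k} \tilde w_{ik} y_{ik}$, with
  design variance
  $\widehat{var} = \frac{1}{n_k}\left(1 - \frac{n_k}{N_k}\right)
  \frac{1}{n_k - 1} \sum_i \tilde w_{ik}^2 (y_{ik} - \hat p_k^{HT})^2$.
  Under simple random sampling within an area the estimator reduces to
  the sample mean (exactly design-unbiased; the test suite verifies
  this by exhaustive enumeration on small populations) and the variance
  collapses to $(1 - n_k/N_k)\,\hat p(1-\hat p)/(n_k - 1)$.

Derived weighted summaries feed the model-based estimators: the
effective sample size $n_k^* = \hat p(1-\hat p)/\widehat{var}$, the
effective number of cases $y_k^E = n_k^* \hat p$, the empirical logit
$y_k^L = \mathrm{logit}(\hat p)$ with variance
$\widehat{var}/(\hat p (1-\hat p))^2$, and the arcsine root
$y_k^A = \sin^{-1}\sqrt{\hat p}$ with variance $(4 n_k^*)^{-1}$.

Degenerate inputs: an estimate of exactly 0 or 1 is truncated into
$[1/(2n_k),\, 1 - 1/(2n_k)]$ before any variance or transform is
computed, keeping the logit and $n^*$ finite; single-record areas have
no variance estimator, so $\hat p'(1-\hat p')$ with the truncated
$\hat p'$ is imputed; variances are floored at $10^{-10}$.  Confidence
intervals for the design-based estimators are Wald intervals truncated
to $[0, 1]$ — published survey analyses rarely state a construction for
these, and Wald-with-truncation is this package's choice.

## Smoothing models

Four likelihood families share one linear predictor with BYM-type
random effects:

| family | data | likelihood |
|---|---|---|
| NB | raw counts | $y_k \sim \mathrm{Bin}(n_k, \tilde p_k)$ |
| LN | empirical logit | $y_k^L \sim N(\mathrm{logit}\,\tilde p_k, \sigma_k^2)$ |
| AS | arcsine root | $y_k^A \sim N(\sin^{-1}\sqrt{\tilde p_k}, \sigma_k^2)$ |
| ES | effective counts | $y_k^E \sim \mathrm{Bin}(n_k^*, \tilde p_k)$ |

with $\mathrm{link}(\tilde p_k) = \beta_0 + u_k + v_k$, unstructured
$u_k \sim N(0, \sigma_u^2)$ and intrinsic CAR
$v_k \mid v_{-k} \sim N(m_k^{-1} \sum_{k' \sim k} v_{k'},\,
\sigma_v^2 / m_k)$ over the shared-boundary adjacency graph, sum-to-zero
constrained per connected component.  The ES denominator $n_k^*$ is
real-valued; the binomial density is continued with log-Gamma factorials
rather than rounded, so it reduces exactly to the binomial pmf at
integer arguments while admitting effective counts as printed.

Subgroup structures for auxiliary data: with a G-category covariate
whose per-area population shares $\pi_{gk}$ are known, the data are
formed per (group, area) cell and the predictor becomes
$\beta_1 + \sum_{l \ge 2} \beta_l I(g = l) + u_k + v_k$ (M3); M1 drops
the spatial terms, M2 drops the covariate, M0 is the area-level
baseline.  Area estimates for M1–M3 are post-stratified per posterior
draw, $\hat p_k = \sum_g \pi_{gk}\, \tilde p_{gk}$.  For the NB family
M2 factorizes into M0 exactly (the subgroup binomials with a common
success probability multiply to the area binomial); the test suite
checks this equivalence numerically.

### Priors and inference

Fixed effects carry flat priors; each precision $1/\sigma^2$ gets a
Gamma(0.5, 0.0005) hyperprior, the conventional disease-mapping default
(configurable).  Inference is single-site Metropolis-within-Gibbs in a
numba-compiled kernel:

* in-sample $v_k$: random-walk Metropolis against likelihood + ICAR
  conditional; off-sample $v_k$: exact Gibbs draw from the ICAR
  conditional (its full conditional, as no likelihood term exists);
* in-sample $u_k$: random-walk Metropolis; off-sample $u_k$: fresh
  $N(0, \sigma_u^2)$ draw each sweep.  Off-sample areas therefore
  inherit the full predictive uncertainty of both effects, which is why
  their credible intervals are wider than in-sample ones;
* scalar random-walk Metropolis for $\beta$'s, plus a joint
  likelihood-invariant shift move $(\beta_0 + \delta, u - \delta)$ that
  decorrelates the intercept from the unstructured field;
* conjugate Gamma updates for both precisions (the ICAR quadratic form
  uses rank $K_v - C$, the number of non-isolated areas minus their
  component count);
* after every sweep $v$ is recentred within each connected component
  and the mean shift is absorbed into $\beta_0$.  For a connected graph
  this is an exact reparameterization onto the constrained space; for
  multi-component graphs the single intercept can only absorb the
  area-weighted overall mean, a documented approximation (all shipped
  geographies are connected).  Isolated areas keep $v_k = 0$ and rely
  on $u_k$ alone.

Proposal scales adapt toward ~44% acceptance during burn-in only.
Defaults are 4 chains × 5000 iterations with 2500 burn-in; the
simulation drivers use 2 chains × 2000 with 1000 burn-in, which the
logit-normal closed-form oracle shows is accurate for these models at
these sizes.  Convergence is summarized by split-chain R-hat and bulk
ESS (via arviz) on the intercept and variance components; R-hat > 1.05
triggers a recorded warning.  Correctness of the sampler is anchored by
two oracles in the test suite: the linear-Gaussian LN model with fixed
precisions against the analytic GMRF posterior (means within 3
Monte-Carlo SE, sds within 5% on a 3×3 lattice), and a
disconnected-areas binomial model against 1-D quadrature.

Prevalence summaries use the inverse link per draw; for the AS family
the latent Gaussian draw is clamped to $[0, \pi/2]$ before applying
$\sin^2$, since the Gaussian likelihood can push draws outside the
range.  Credible intervals are equal-tailed 2.5%/97.5% quantiles.

## Synthetic data generator

The generator emulates the structure of a national household survey
over 125 districts; it does **not** reproduce any real geography,
adjacency, population register or microdata.

* Geography: a 5×25 rook lattice stands in for the district map.
* Populations: lognormal area sizes (log-sd 0.75) scaled to 20 million
  — order-of-magnitude area-to-area variation typical of districts.
* True prevalences: $\mathrm{logit}(p_k) = \alpha + s_k + e_k$ with the
  structured effect $s_k$ drawn from the zero-mean constrained ICAR
  (via eigendecomposition of the structure matrix) and $e_k$ iid
  normal.  Scenario variance pairs (iid, ICAR): A1 (0.15, 0.03), A2
  (0.09, 0.09), A3 (0.03, 0.15) — weak, mild, strong spatial structure.
  $\alpha = 0$ for the missing-areas design.
* Design 1: stratified SRS with proportional allocation of n = 16,000
  (largest-remainder rounding, minimum 2 per area so the design
  variance exists), weights $N_k/n_k$; per replicate, m areas are
  removed uniformly.  Effects (hence $p_k$) are drawn once per scenario
  and held fixed across replicates.
* Design 2: 858 synthetic enumeration areas (EAs) apportioned to areas
  proportional to $N_k^{2.7}$ (minimum 1), each urban with probability
  0.25 and holding 120 households; 86 urban and 135 rural EAs are
  sampled by SRS within stratum, then 12 (urban) / 9 (rural) households
  per EA.  Weights are inverse inclusion-probability products.  The
  concentration exponent is calibrated once so that roughly half the
  areas receive no EA, matching the ~52% off-sample share of the
  motivating survey.  Outcomes follow B1 (spatial only) or B2 (spatial
  + 8-category covariate); because the fitted coefficients behind the
  published second design were never printed, the defaults are
  $\alpha = 1.1$ (a ~75% national prevalence) and covariate offsets
  evenly spanning $[-1, 1]$, both configurable.
* Compositions: Dirichlet draws around the published energy-source
  shares (concentration chosen for wide area-to-area ranges), then a
  few iterative-proportional-fitting passes so across-area means match
  the published column within 2% while rows stay on the simplex.

What the generator does not emulate: non-response, household clustering
of outcomes within EAs beyond the shared $p_k$, measurement error, or
real adjacency irregularities (islands, coastal gaps).  Passing tests
therefore demonstrate correctness of the estimators and the qualitative
behaviour under the stated designs, not performance on any specific
real survey.

## Evaluation

Per grid cell and stratum (in-/off-sample, membership per replicate
since the removed set varies): squared bias
$(1/K)\sum_k (\bar p_k - P_k)^2$, MSE
$(1/K)\sum_k S^{-1}\sum_s (\hat p_k^{(s)} - P_k)^2$ (both averaging
within area first, which preserves MSE ≥ Bias²), coverage pooled over
(replicate, area) cells, and mean interval length.  Design-based
estimators are scored in-sample only.

Problem sizes for the shipped reproduction run: 125 areas, S = 25
replicates, m ∈ {10, 30, 50, 70}, scenarios A1–A3, four families at 2
chains × 2000 iterations — the package's desk-scale profile (the
original experiment used S = 100, available via configuration).  At
S = 25 the off-sample squared-bias curve in m is flat within
Monte-Carlo error (areas removed at small m contribute only one or two
replicates each, so the pooled bias estimate absorbs sampling noise);
the trend test therefore asserts the rise-then-plateau shape with
batch-estimated Monte-Carlo tolerances.

## Known limitations

* The multi-component sum-to-zero compensation is approximate (see
  above); fit results on graphs with several non-trivial components
  should be interpreted with care.
* Post-stratified design-based estimates renormalize composition
  fractions over the groups actually observed in an area's sample;
  areas missing entire heavy groups inherit that bias (visible as the
  degraded design-based performance under sparse subgroup cells).
* Single-site Metropolis mixes slowly for very strong posterior
  correlations (e.g., near-zero likelihood information with large K);
  the shift move mitigates the intercept/field coupling but chain
  lengths should be raised for weakly-informed fits.
* No non-response modelling; weights are assumed final.
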