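# Methods

## Model and estimation

### Single-species occupancy

Each site i has latent occupancy z_i ~ Bernoulli(Ψ_i); conditional on
z_i = 1, the K survey outcomes are independent Bernoulli(p_i). Surveys are
the marker genes of one panel, so the closure assumption (the occupancy
state cannot change between surveys) holds by construction: all markers
are screened in the same DNA extraction. The likelihood marginalizes z_i,
giving the two-branch site likelihood in the README. Both Ψ and p use
logit links — the standard choice for this model family — with linear
predictors over the term vocabulary {1, ecosystem, latitude,
sqrt(numeric.add.date)}.

Fitting is direct maximum likelihood: BFGS with an analytic gradient, from
the zero vector plus four seeded N(0, 0.5²) starting perturbations (five
starts by default; the seed is recorded in the fit). BFGS occasionally
reports "precision loss" at a genuine optimum, so convergence is judged by
the score: a fit is converged when the optimizer succeeds or the gradient
infinity-norm at the optimum is below 1e-4 · max(1, |ℓ|). Standard errors
come from the inverse observed information, computed as a numerical
Hessian at the optimum; when that matrix is near-singular a pseudo-inverse
is used and a warning attached. Wald intervals for Ψ and p are formed on
the linear predictor and mapped through the inverse logit, so they always
lie inside (0, 1) and contain the point estimate.

Degenerate inputs are flagged, not hidden: fitted probabilities within
1e-6 of 0/1 set a boundary flag (perfect-detection data drive Ψ̂, p̂ → 1);
K = 1 leaves only the product Ψ·p identifiable and adds a warning; a
species never detected anywhere fits but carries a non-identifiability
warning. Rank-deficient designs are an error naming the columns.

Covariates are deliberately not standardized, and sqrt(numeric.add.date)
enters as-is; AIC comparisons are unaffected and coefficients stay on
interpretable scales.

### Two-species occupancy

The joint latent state follows the log-linear multivariate Bernoulli
P(z1, z2) ∝ exp(z1 f1 + z2 f2 + z1 z2 f12), each natural parameter with
its own covariate design; f12 = 0 recovers independence exactly (the
maximized two-species log-likelihood then equals the sum of the two
single-species ones, which the tests verify to 1e-4 via the
`fix_f12_zero` option). State probabilities are computed with
max-subtraction so large natural parameters cannot overflow. Detection is
intercept-only per species; richer detection structure in the two-species
model is out of scope. Optimization uses multi-start L-BFGS-B with
numerical gradients, the Hessian as above. |f12| > 10 anywhere on the
fitted surface triggers a quasi-separation warning; no penalization is
applied.

Conditional occupancy P(z1 = 1 | z2 = ±) is a ratio of sums of the four
state probabilities. Its interval defaults to a parametric bootstrap
(1,000 seeded draws from the coefficient vector's normal approximation)
because the delta method can misbehave for a ratio near the boundary; a
delta-method alternative propagates variance on the logit scale, and the
tests check the two agree within 0.05 at N = 3,000. Either construction
keeps intervals inside (0, 1).

### AIC

AIC = −2ℓ + 2k with k the total number of design columns (plus the two
detection intercepts in the two-species model); comparison tables sort
ascending with ties in input order. The ecosystem factor is encoded
against the lexicographically first level present ("engineered" for the
standard three categories); the likelihood and AIC are invariant to this
labeling, which the tests assert to 1e-6.

## Sites, aggregation, covariates

Three site definitions are supported: each metagenome its own site;
metagenomes grouped on identical recorded geocoordinates; and the same
grouping additionally split by ecosystem category (samples from different
ecosystems at one coordinate — a rumen and the soil beneath it — are not
one community). Grouping keys are the *textual* coordinates, trimmed but
never rounded: rounding would silently merge distinct sites. Detections
OR across members. Aggregated-site covariates: ecosystem is uniform by
construction where it is part of the key and is not emitted for the
coordinates-only scheme; the numeric add date of an aggregate is the
earliest member's date; latitude comes from the shared coordinates.
Sample date never participates in grouping, but the aggregation result
reports how many multi-member sites mix sample dates. Missing metadata is
handled by listwise removal only — no imputation.

The add-date covariate counts days from 2006-01-01 (epoch ↦ 0; earlier
dates are an error, not clamped) and enters models square-root
transformed.

## Curation

The length window derives from true-positive references only (false
positives describe what to exclude, not the target family): minimum
true-positive length − 50 aa, floored at 1, to maximum + 50, inclusive.
The top-hit stage keeps a query only when its maximum-bit-score subject is
a labeled true positive; on exact score ties every tied subject must be a
true positive — the conservative resolution under a no-false-positives
assumption. Queries absent from the hit table are removed (reason
`no_hit`): missing homology evidence cannot certify a true positive.
Exclusion of ANME-type MCR is label-based — those references are labeled
false positives — so both the top-hit and tree stages enforce it without
needing a distance threshold.

The tree screen replaces manual phylogenetic judgment with an explicit
heuristic: flag a query when its nearest labeled leaf by patristic
distance is a false positive (ties broken lexicographically for
determinism), or when its terminal branch exceeds median + c·MAD over all
terminal branches, c = 6 by default, configurable and logged. Raising c
can only grow the kept set. The MAD rule is a pragmatic operationalization
of "excessively divergent", not a reconstruction of any particular manual
protocol; likewise no e-value or score threshold is imposed on the hit
table by default — the classification uses ranks, not cutoffs, and any
upstream search thresholds should be documented by the caller.

## Synthetic data

The generators draw covariates (ecosystem with probabilities
0.806/0.133/0.062 for environmental/host-associated/engineered —
renormalized from rounded percentages that sum to 100.1 — latitude
uniform on [−60, 75], add date uniform on 0–5,000 days), then latent
states through the same link functions the models fit, then detections.
One seeded generator drives all draws in a fixed order, so a seed pins
every artifact. The generators emulate the marginal composition of a
large public-database survey; they do not reproduce spatial clustering,
the sampling bias toward North America and Europe, survey-varying
detection, or real sequence evolution — so passing tests demonstrate
correct inference under the stated model, not robustness to those
real-data features.

The curation fixture is a hand-constructed single-marker panel (~21
candidates) whose disposition ledger covers every reason code; reference
and candidate sequences are random amino-acid strings of the required
lengths (sequence content is irrelevant to the screens, which consume
lengths, hit tables, and trees).

`recovery_experiment` repeats simulate → fit and reports per-parameter
bias, RMSE and 95% Wald coverage; non-converged replicates are counted
and excluded, never fatal.

## Problem sizes

The reference experiments use N = 20,000 sites for the naive-vs-model
comparison (keeps the Monte Carlo error of the naive fraction near
0.001), 500 replicates of N = 500 for calibration (binomial error on a
95% coverage estimate ≈ 1 point), and N = 3,000 for two-species recovery
(SE of f12 ≈ 0.15, small enough to make a 3-SE check informative). These
sizes were chosen once as the package's reference conditions.

## Known limitations

- No false-positive-augmented occupancy variants, Bayesian fitting,
  spatial autocorrelation corrections, or multi-season dynamics.
- Two species only; no dominance-structured co-occurrence models.
- Detection covariates are site-level; survey-varying detection is not
  modeled.
- Geographic aggregation requires exactly identical recorded coordinates;
  no geodesic clustering of nearby points.
- Coefficient-scale comparisons to external fits of the same data require
  identical factor codings; AIC and likelihood are coding-invariant but
  individual coefficients are not.
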