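# Methods

## Mixing model

Dietary grass fraction is the linear mixing coordinate of an
enamel-equivalent δ13C value between two endpoints: f_C4 = (δ − e3)/(e4 −
e3), where e3 = δ13C_C3 + ε and e4 = δ13C_C4 + ε. Defaults are the mean
tropical-African plant values δ13C_C3 = −26.6‰, δ13C_C4 = −10.0‰ and an
enamel enrichment ε = +14.1‰, giving e3 = −12.5‰ and e4 = 4.1‰. All three
constants live in `MixingConfig`, so other tissue systems or sensitivity
analyses only need a different config. Inputs must already be
enamel-equivalent; tissue conversions (hair keratin, collagen) are out of
scope.

Measured values can fall slightly outside the endmember interval
(analytical noise, atypical local vegetation). Fractions outside [0, 1]
are not physical, so by default they are clamped to the nearer bound, with
the raw value retained and a per-sample flag raised; clamping can be
disabled. A community is auto-excluded as "no within-community diet
variation" when every species mean fraction is ≤ 1e-9 — the tolerance
absorbs float noise at the C3 endpoint (−26.6 + 14.1 = −12.500000000000002
in binary floating point).

## Diet tables

Local estimates are per (species, community) means with n−1 SDs; regional
estimates pool the species' samples across all communities; global values
come from the traits table for species never sampled. Fill-in priority is
strictly local > regional > global, and a species with local samples but
missing from the occurrence list is treated as present. Body mass is
log-transformed with the **natural** log (the slope scale is
logit-fraction per ln kg; recorded in output metadata since slopes are
base-dependent).

Inverse-variance weighting needs finite positive SDs. Cells with one
sample or zero spread borrow the species' regional SD, then the median of
all positive SDs in the table — a pragmatic fallback chosen so weights
exist without discarding data; the weight transform is recorded in the fit
report. Community means (mean_C4) are unweighted species means: the
occurrence data carry no abundances, so any abundance weighting would be
invented.

## Weighted beta regression

The response is strictly inside (0, 1) after the boundary adjustment
0 → .001, 1 → .999. The joint model has a per-community intercept and
per-community log-mass slope (and log-mass² column when the parabolic
order is requested) with a single precision φ, so k = (order+1)·C + 1.
Communities with fewer than two distinct masses cannot carry a slope and
are dropped with a warning.

The weighted log-likelihood Σ w_i log Beta(y_i; μ_i φ, (1−μ_i) φ) is
maximized by BFGS with the analytic gradient from a weighted
least-squares start on logit(y) (method-of-moments start for φ), followed
by Newton polishing until the gradient norm is below 1e-6; failure raises
an error carrying the last iterate. The coefficient covariance is the
inverse observed information (numerical Hessian of the analytic
gradient). Weights from SDs use w ∝ 1/sd² (inverse-variance convention;
1/sd available as a sensitivity option) and are normalized to mean 1, so
fits are invariant to rescaling all SDs and the weighted log-likelihood
stays on the unweighted scale. Wald p-values use the standard normal; the
p < .1 "robustly directional" threshold is reporting-only, never a
filter.

Fit metrics: AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1); RMSE on the fraction
scale; pseudo-R² is the squared Pearson correlation between logit(y) and
the linear predictor (the convention of standard beta-regression
software). Order selection compares AICc of the linear and parabolic
fits; ties break to linear.

## Ordination

Community composition enters as the first two axes of a classical PCoA of
pairwise Jaccard dissimilarities. The Gower double-centering of −½D∘D is
eigendecomposed symmetrically; axes with non-positive eigenvalues are
excluded from scores but reported, along with the negative-eigenvalue
share, as a diagnostic — no Lingoes/Cailliez correction is applied. Axis
sign is mathematically arbitrary, so each axis is oriented to make its
largest-magnitude score positive; published ordinations may therefore be
flipped relative to ours, and downstream coefficient signs on PCoA axes
should be read with that in mind. Covariate vectors are least-squares
projections of z-scored covariates onto axes 1–2.

## Second-stage model selection

Responses: per-community slope (weights 1/SE²), community-mean grass
fraction (unweighted — the mean carries no single SE comparable across
communities), and per-species fractions across communities (weights
1/SD², species restricted to ≥12 communities with local data). Predictor
sets: environment {MARain, RainS, MATemp, TempS, Woody_cover, MARain²,
Woody_cover²}, community {PCoA1, PCoA2, SpN, mean_C4, Elephant}, and
their union; mean_C4 is removed when it is the response. Continuous
predictors are z-scored before enumeration and polynomial terms are raw
squares of the standardized base (coefficients stay comparable; the
hierarchy rule admits a square only with its base term).

A pair of predictors is forbidden when |r| > .5 **and** the correlation
is significant at α = .05; a square is never forbidden against its own
base. All subsets free of forbidden pairs are fitted; subsets too large
for the sample (n ≤ k+1, AICc undefined) are skipped with a warning.

Spatial structure: residual correlation is a function of great-circle
(haversine) distance in km — none, exponential exp(−d/r), gaussian
exp(−(d/r)²), or spherical with range r and zero nugget. For each model
set the structure minimizing AICc on the global model (forbidden pairs
resolved by greedily dropping the member with the larger mean absolute
correlation to the other terms; second-order terms trimmed first if the
sample cannot support the full global model) is fixed for all candidate
models; ties break none > exponential > gaussian > spherical. Estimation
is maximum likelihood with β and σ² profiled out and the range optimized
on a log scale in [1, 20000] km; k counts coefficients, σ², and the range
when present. Weights enter as per-observation variance scalers 1/w.
Inference is purely information-theoretic: the plausible set is
ΔAICc < 2, summarised by per-term appearance counts and sign consistency.
No p-value-based selection occurs anywhere.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, at
study scale: 23 communities, a 57-species pool with log-uniform masses
1–4500 kg, ~25 species per community, 1–10+ isotope samples per
species-community cell (Poisson mean 5, min 1), and 25% of cells withheld
to exercise regional/global fill-in. Covariates: MARain ~ U(200, 1600)
mm; woody cover built from standardized MARain plus independent noise
(target r ≈ 0.6, the rain–tree-cover collinearity of real savannas),
scaled to span the real gradient from semi-desert (~0.05) to closed
forest (~0.9); RainS, MATemp, TempS independent uniforms over realistic
East-African ranges; coordinates on a 15° box.

True community slopes follow b_c = 0.6 − 0.3·z(RainS) − 0.5·Elephant +
N(0, 0.1) (logit per ln kg, standardized predictors); intercepts follow a
downward parabola in woody cover peaking at 0.5 (curvature 6 on the logit
scale, i.e. community-mean grass dependence falls from ~0.5 at the peak
to ~0.25 at the gradient ends — the magnitude of contrast seen across
real communities). Species below 10 kg are capped at a browsing-level
fraction (0.15) and the elephant (Loxodonta, >3000 kg) is fixed at a low
grass fraction (0.2), mirroring the near-universal browsing of small
herbivores and the browse-dominated diet of modern elephants. Simulated
δ13C values are the inverse mixing model plus Gaussian noise (1.5‰),
*truncated* to the endmember interval — truncation rather than clamping
keeps samples physical without piling probability mass on the endpoints.

What the generator does **not** emulate: phylogenetic structure in the
species pool, abundance/biomass structure, seasonal or temporal sampling,
spatially autocorrelated covariate fields, and taxonomy noise. Passing
recovery tests therefore demonstrates that the estimators recover the
generating process under the stated noise model, not that the field data
satisfy that model.

Elephant presence in the second-stage predictor table is taken from the
occurrence list as well as the diet table: presence is external knowledge,
and a sampled species list can miss an elephant population that is known
to be there.

## Problem sizes in the test suite

Unit tests run on 2–10 community instances. The statistical acceptance
checks use 20 random instances for the optimizer-equivalence oracle, 200
replicates (10 communities × 20 species) for Wald-interval coverage, and
50 seeded study-scale replicates for full-pipeline qualitative recovery
with the per-species models switched off (they exercise the same
second-stage code path already covered elsewhere). These sizes give
stable pass/fail behaviour at matched statistical power while keeping the
default run fast.

## Known limitations

* Constant precision φ across communities; no variable-dispersion or
  bias-corrected beta regression.
* The Wald covariance is the inverse observed information of the weighted
  likelihood; under strongly misspecified weights a sandwich estimator
  would be more robust.
* Second-stage models are fixed-effects GLS; no REML, mixed effects, or
  model averaging of predictions.
* Exact-string species matching (with a user-editable synonym map) —
  no taxonomic reconciliation.
* The weight transform (1/sd² vs 1/sd) and the pseudo-R² definition are
  conventions, recorded in output metadata, and switchable where
  alternatives are defensible.
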