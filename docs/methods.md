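# Methods

## Model

A twin pair's phenotype vector — two traits at up to two waves per twin,
eight variables at most — is modelled as multivariate normal with a
covariance built by path tracing.

**Within-time structure.** Each trait loads on its own additive-genetic
(A), shared-environment (C) and non-shared-environment (E) latent
factors with loadings a, c, e; the variance contributed by a source is
the squared loading.  Twin sharing: same-trait co-twin correlation on A
is 1 for MZ and 0.5 for DZ pairs (the additive-genetic sharing rule),
on C it is 1 for both, on E it is 0.  Cross-trait covariation is
parameterized by correlated factors — the latent correlations rA, rC,
rE between the two traits' same-source factors — rather than a Cholesky
decomposition, because the correlations themselves are the quantities
of scientific interest.  Cross-twin cross-trait A covariance is rA·a1·a2
for MZ and half that for DZ; C analogously with sharing 1; E contributes
nothing across twins.  The within-person cross-trait correlation is the
path-traced sum rPh = rA·a1·a2 + rC·c1·c2 + rE·e1·e2; because the latent
sources are mutually orthogonal, each term is the part of rPh mediated
by that source, and term/rPh is the bivariate a²/c²/e² share.

**Cross-wave structure.** Within each twin, the time-2 phenotype pair is
a linear regression on the time-1 pair through B = [[b11, b21],
[b12, b22]] (b11/b22 continuity, b12/b21 cross-lags; b12 is variable 1 →
variable 2), plus an ACE-structured residual with its own loadings and
latent correlations, orthogonal to all time-1 latents (the standard
cross-lag assumption; no direct latent-to-residual paths).  The pair
covariance is assembled as Σ_t1, B-propagated blocks Σ_t1·Bᵀ and
B·Σ_t1·Bᵀ + Σ_res, with the same twin-sharing rules inside Σ_res.  For
any latent correlations in [−1, 1] the construction is positive
semi-definite (each source's latent covariance is a Kronecker product of
PSD matrices); the moment builder still verifies eigenvalues and reports
the offending one if a covariance is forced non-PSD.

**Derived estimands.**  Time-2 influences are reported on *total*
variance: for each source, the transmitted covariance B·Σ_t1,S·Bᵀ
(crediting the covariance of the two transmitted streams to the source
that generates it) plus the residual source covariance, divided by total
time-2 variance; total-scale latent correlations divide the
cross-variable source covariance by the geometric mean of the source
variances.  The continuity R² is simply b² for a standardized path.

## Estimation

Estimation is full-information maximum likelihood: each pair contributes
the Gaussian log-density of its observed subvector, so pairs missing the
entire second wave (or any other pattern) remain informative.  The
evaluation groups pairs by missingness pattern and reduces each group to
count, mean and scatter, making a likelihood evaluation O(patterns), not
O(pairs); on complete data this *is* the closed-form sufficient-statistic
likelihood, and a per-row reference path cross-checks it.

The optimizer works on an unconstrained scale: loadings are free reals
(squared into variances) and latent correlations pass through tanh.
This avoids boundary-constrained optimization; the cost is reflection
symmetry (only squares and sign-consistent products are identified), so
all reported quantities — variance shares, sign-corrected correlations,
standardized paths — are invariant to the reflections.  L-BFGS-B with
numerical gradients is run from a default start plus seeded perturbed
restarts (default 5) to guard against local optima; convergence uses
gradient tolerance 1e−5 and relative function tolerance 1e−9, both
configurable.  Twin exchangeability is imposed by the model structure
(no twin-order parameters), never by double-entering pairs, which would
inflate the apparent sample size.

Data are z-scored per variable per wave (pooled over twins) before
fitting, and a rank-based inverse-normal transform is available for
skewed scores but is not the default.  Fitted loadings are standardized
to variance shares when reported; lag paths are standardized by the
model-implied source and target SDs.  Means are freed per variable and
wave (equated across twin order and zygosity by model structure), which
spends 2 parameters per variable-wave on the z-scored scale.

**Confidence intervals.**  The default is profile likelihood: an
endpoint is the parameter value at which the re-optimized −2lnL exceeds
the minimum by the χ²(1) quantile (3.841 at 95%), located by outward
bracketing and bisection.  Probe refits use two starts (the MLE and a
warm chain along the profile) plus one perturbed restart, because a
loading stuck at exactly zero is a stationary point of the squared
parameterization and a single gradient start cannot leave it; bisection
with a likelihood tolerance is used instead of a derivative-aware root
finder because probe values carry optimizer noise of order 1e−5.  When a
bound cannot be bracketed inside the parameter space (correlations at
±1) the interval is flagged one-sided.  Wald intervals from the
numerical Hessian (delta method through the tanh link) are also
available; the two agree in the quadratic limit.

**Model comparison.**  The saturated baseline frees a mean vector and a
triangular-factor-parameterized covariance per group (zygosity, or
zygosity × sex with same-sex male/female and opposite-sex DZ groups) —
with complete data it is solved in closed form.  Nested models are
compared by likelihood-ratio χ² with df equal to the difference in free
parameter counts; `equate_paths_test` fits free-versus-equated variants
of a path pair (the reciprocal-influence question).  BIC is
−2lnL + k·ln(n_pairs); pairs, not individuals, are the independent
sampling units — this convention changes absolute BIC values but not
comparisons within one dataset.  Full sex-limitation models are out of
scope; the provided descriptive check fits the structured model pooled
versus stratified by sex on same-sex pairs only (a valid nesting), while
the main no-sex-difference models pool opposite-sex DZ pairs with
genetic sharing 0.5.

## Simulator

The generator draws each pair's phenotype vector from the implied
multivariate normal of its zygosity and masks the whole time-2 block of
a random subset of pairs, emulating a two-wave study in which only a
representative fraction of families (default retention 0.31) is
re-assessed.  Missingness is therefore MCAR at the pair level; a hook
accepts a user-supplied retention-probability function of the time-1
scores for attrition sensitivity analyses, but phenotype-dependent
attrition is deliberately not the default.  Sexes are assigned
identically within MZ and independently within DZ pairs and feed only
the descriptive layer.  Identical seed, design and parameters give
bit-identical datasets.

Default generating values mirror the adolescent
depression–psychotic-experience literature: depression time-1 shares
.26/.14/.60; paranoia .50/.12/.38; hallucinations .45/.10/.45; cognitive
disorganization .45/.12/.43; genetic correlations with depression
.78/.68/.78 with rC in .45–.55 and rE in .30–.40 (the paranoia values
rC=.45, rE=.40 make the implied depression–paranoia correlation .53 and
its decomposition .53/.11/.36); continuity paths .48 (depression), .55,
.56, .63, and cross paths .14/.15 (paranoia), .09/.14 (hallucinations),
.11/.20 (cognitive disorganization).  Residual time-2 variances are
solved so every time-2 total variance is 1; residual ACE shares and
latent correlations default to the time-1 values.  Phenotypes are
generated on the standardized scale; an affine post-transform to
questionnaire-like ranges (0–26 depression, 0–72 paranoia, 0–45
hallucinations, 0–11 cognitive disorganization) exists purely for I/O
realism and is not used in analyses.

**What the simulator does not emulate.** Real questionnaire scores are
bounded, discrete and right-skewed, attrition may depend on symptom
levels, zygosity can be misclassified, and assortative mating or
sibling interaction would distort the 1/0.5 sharing rules.  Passing
recovery tests therefore demonstrate that the estimator inverts its own
generating model at study scale — a necessary correctness property —
not that real-data estimates are unbiased under those violations.

## Numerical choices and problem sizes

Candidate covariances that fail Cholesky factorization during
optimization receive a large penalty value rather than an exception;
the final fit re-validates.  Saturated starts use pairwise-complete
moments eigenvalue-floored to positive definiteness.  The LRT guards
against termination noise by polishing the free fit from the constrained
optimum whenever the constrained −2lnL lands below it, and advises a
refit if a genuinely negative statistic beyond 1e−6 remains.  Degenerate
inputs are rejected with specific messages: duplicate family IDs,
unknown zygosity tokens, non-numeric cells (by row), all-missing rows,
groups too small for an identified saturated model, singular
observed-pattern submatrices (named by pattern).

Test and acceptance problem sizes are chosen so the full suite runs in
minutes: recovery tests use the study-scale designs (5000+5000 pairs
one-wave; 3300 MZ + 4700 DZ with 31% retention two-wave); the
Monte-Carlo moment oracle uses 2×200k–400k pairs with joint 3–4 SE
bands; LRT type-I calibration uses 200 replicates of 800+800 complete
pairs (calibration does not depend on n); profile-CI coverage uses 50
study-scale replicates, assessed on the identified a² scale.  The
acceptance script averages each reported quantity over 3–5 replicate
simulate-and-fit runs because single-draw sampling SDs (e.g. ~0.055 for
a genetic correlation at 5000+5000 pairs) are comparable to the recovery
tolerances themselves.

## Known limitations

No dominance (ADE) or qualitative sex-limitation models; two traits and
two waves only; continuous phenotypes only (no liability-threshold
ordinal models); no robust/sandwich standard errors or bootstrap CIs;
profile CIs are reported for parameters, not propagated through every
derived estimand.  The saturated model frees all moments per group and
so does not impose twin exchangeability, matching the conventional
baseline; its −2lnL is therefore a lower envelope rather than a
structured alternative.
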