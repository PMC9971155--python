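# Methods

`dyadnet` implements a complete dyadic social-bonding analysis for
focal-sampling data from group-living animals: association indices from
daily-binarized observation streams, hurdle beta/binomial mixed models on
those indices, datastream permutation inference for group-by-dyad-sex
effects, and weighted sociograms with Potts-model community detection. This
note records the model, the numerical choices, and what the synthetic-data
tests do and do not establish.

## Observation model and the simple-ratio index

A focal sample follows one individual for a fixed interval and records every
group member within 10 m ("party co-residence"), within 1 m ("direct
association"), and every grooming partner (giving or receiving pooled). To
maximize independence between sampling periods, each stream is binarized by
calendar date: a dyad scores 1 on a day if it was observed associating at
least once that day, from either member's focal samples, else 0.

The tie strength of a dyad is the simple-ratio index

    SRI = x / (x + Y_AB + Y_A + Y_B),

where `x` counts days the pair was observed associated, `Y_A` and `Y_B`
days with only one member identified, and `Y_AB` days with both identified
but not associated. An individual is "identified" on a day if it was focal
at least once or appeared in any focal's 10 m set — the most inclusive
reading of gambit-of-the-group focal data. Identification is
measure-independent, so the three streams share denominators and are
nested: SRI(grooming) <= SRI(1 m) <= SRI(10 m) whenever the recorded sets
are nested. Dyads never identified on any day receive SRI 0 with a logged
flag rather than being dropped, keeping matrices total.

## Hurdle mixed models

Party co-residence indices are modelled directly with a beta GLMM (logit
link; density parameterized by mean mu and precision phi). Direct
association and grooming are sparse — typically more than half of the dyads
have index 0 — so each is modelled as a hurdle: a Bernoulli GLMM for
whether any association occurred, then a beta GLMM for the magnitude among
the nonzero dyads. Fixed effects are dyad sex type (FF/MF/MM) in
interaction with group, plus maternal kinship (binary) and absolute age
difference (years) as covariates. Each unordered dyad contributes one row;
non-independence from shared individuals is absorbed by two random
intercepts per row, one for each member.

Two random-effect layouts are supported: *crossed* (default), with separate
intercept vectors and variances for the member-A and member-B roles, and
*multi-membership*, a single per-individual intercept vector entering
additively through both roles with one variance. The canonical member order
is lexicographic, so role variances are not interchangeable with individual
identities; the multi-membership layout is the cleaner interpretation when
role asymmetry is implausible, and the two give near-identical inference on
the synthetic data.

Boundary indices (0 or 1) are compressed into the open interval with the
standard transform `y' = (y(n-1) + 0.5)/n` before beta fitting, applied per
model only when boundary values are present and always logged.

### Estimation

The marginal likelihood integrates the latent intercepts out by a Laplace
approximation. An inner penalized Newton solve locates the joint mode of
the latent effects (expected-information step first, exact observed Hessian
afterwards, with step halving); the curvature correction uses the exact
observed Hessian of the conditional log-likelihood, floored positive. The
outer parameters (log phi and log sigma per role) are maximized by
Nelder-Mead, with the fixed effects profiled into the inner solve for
speed; the default fitting path then polishes all parameters jointly
against the standard Laplace objective, which moves estimates at the third
decimal and keeps the model ladder's maximized log-likelihoods monotone.
`marginal_loglik(..., method="gh")` evaluates the same integral by dense
tensor-product Gauss-Hermite quadrature (feasible up to six latent
dimensions) and is used in the tests as the accuracy oracle: on tiny
instances at the model's operating point (sigma 0.3-0.5, phi 8-30) the two
agree within 0.01-0.05 nats. The Laplace error grows with sigma and with
fewer observations per latent dimension, a known property of the
approximation rather than of this implementation.

A fit is declared converged only if the joint gradient norm is below 1e-4
and the outer simplex has collapsed below 1e-8 in relative function value;
non-convergence triggers up to five deterministically jittered restarts and
is always reported, never silenced. Fixed-effect covariance is the inverse
of the exact joint Hessian's fixed-effect block (conditional on phi and the
variance components). Variance components may legitimately fit to zero;
`fix_sigma_zero` pins them there, in which case the fit reduces to plain
ML and matches statsmodels' beta regression to 1e-6 on the test fixtures.

### Model comparison and contrasts

The group-by-dyad-sex interaction is tested by comparing the full model
against a reduced model with the mains retained: chi2 equals the deviance
difference, df = 2 for a 3-level by 2-level interaction, with the analytic
chi-square tail probability alongside the permutation p-value below.
Per-sex-type group contrasts are estimated-marginal-mean differences on the
link scale (first group minus second, kinship at 0, age difference at its
sample mean, which both cancel in the difference), with delta-rule standard
errors and two-sided normal p-values. No degrees-of-freedom correction
(Satterthwaite/Kenward-Roger) is applied, and no multiple-testing
correction is applied across measures or hurdle parts.

## Datastream permutations

Observational association data carry sampling biases (uneven observability,
gregariousness), so the interaction is also tested by prenetwork
permutation: within each day, the observed daily events are reassigned
uniformly at random across the dyads that had at least one member
identified that day. Per-day event counts — and therefore every SRI
denominator — are conserved exactly. Each permuted stream is condensed into
indices and refitted with the same full/reduced pair; the p-value is

    P_rand = #(delta_obs <= delta_perm) / n_kept,

reported as "< 1/n" when no permuted value reaches the observed one.
Non-convergent permuted fits are dropped and counted (never redrawn, which
would bias the null), with a warning above 10%. A swap-based scheme that
additionally preserves each individual's daily association count is
available behind `scheme="degree-preserving"`.

Inside the permutation loop the deviance difference uses a profiled
nuisance: phi and the variance components are estimated once per dataset
under the reduced model and the full model's coefficients are refitted at
those values. This statistic is applied identically to the observed and
every permuted dataset (so exchangeability is preserved), is structurally
non-negative, and costs one outer search plus one inner solve per
iteration; it differs from the full-ML LRT chi2 reported by the analytic
path by a small amount that cancels between observed and null draws.
Magnitude (hurdle) responses rebuild their design each iteration because
the nonzero-dyad subset changes under permutation.

Calibration: with all dyad-level effects zero the generator's streams are
exchangeable under the day-conditional reassignment, and the test's
rejection rate at alpha = 0.05 is 4-6% over hundreds of replicates (the
acceptance suite runs 200 replicates of 200 permutations at two groups of
5M+5F over 20 days). The day-conditional null degenerates when daily events
approach saturation (nearly every eligible dyad associated every day);
at realistic association densities (baseline index ~0.1-0.2) it is well
calibrated. When individual gregariousness or kin structure is present the
permutation null absorbs them into the rejection region by design — that is
the method's stated purpose (guarding against observability bias), not a
defect of this implementation.

## Synthetic-data generator

The generator emulates the study's observation process so every stage can
be verified against known ground truth. Two groups with configurable
demographics (defaults: a 22-member group of 11 M + 11 F with 9 maternal
lines and a 39-member group of 10 M + 29 F with 14 lines, reproducing
realistic kin-dyad fractions such as 17 kin dyads among 231); 60 observation
days with each individual focal-sampled often enough to accumulate ~20
focals; per focal sample, each same-group partner joins the 10 m party with
probability

    inv_logit(beta0 + beta_sextype[group, sextype] + beta_kin*kin
              + beta_age*|age_a - age_b| + u_i + u_j),

with `u ~ N(0, sigma_indiv^2)` drawn once per individual and held for the
season (matching the random-intercept model fitted downstream). Partners
enter the 1 m circle independently with `p_close_given_party` and grooming
is drawn only within the 1 m circle, so the three streams are nested by
construction. Defaults: `beta0 = -1.7` (party SRI ~0.1-0.15 per season),
`beta_kin = 1.0`, `beta_age = -0.01`/year, `sigma_indiv = 0.4`,
`p_close_given_party = 0.08` and `p_groom_given_close = 0.5`, which place
more than half of direct-association and about three quarters of grooming
indices at zero — the sparse regime that motivates the hurdle models.
Everything is deterministic given the config seed.

What the generator does *not* emulate: fission-fusion party dynamics,
dominance, estrous cycles, temporal autocorrelation beyond the shared
intercepts, or observer error. Passing tests therefore establish that the
pipeline recovers effects under its own assumptions, not that those
assumptions hold for any particular field dataset.

Note one deliberate asymmetry: the generator applies sex-type effects per
focal sample, while the models act on season-level indices after daily
binarization; generating coefficients are therefore attenuated, not
reproduced one-to-one, on the index scale. Parameter-recovery tests check
sign, coverage, and detection rates rather than numerical equality of
coefficients.

## Sociograms

Graphs take one node per individual (female/male display classes) and one
edge per dyad with positive index, weighted by the index; no display
threshold is applied by default. Layout is weighted Fruchterman-Reingold
(igraph), deterministic given the seed. Communities minimize the
Reichardt-Bornholdt Potts Hamiltonian with the configuration null model,

    H = - sum_{i<j} (w_ij - gamma * s_i s_j / (2m)) * delta(c_i, c_j),

by simulated annealing (gamma = 1, up to 25 spins, geometric cooling from
T = 1 by 0.99 to 0.01, three seeded restarts, greedy descent to a local
optimum afterwards). Disconnected graphs are processed per component with
the null model computed within components; edgeless components are
singleton communities. On graphs of up to ten nodes the annealer matches
exhaustive partition search essentially always (>= 95% of seeded runs in
the acceptance suite).

## Problem sizes used by the test suite

The heavy simulation tests run at reduced sizes chosen for a single CPU:
type-I calibration at two groups of 5M+5F over 20 days (200 replicates x
200 permutations); power and contrast-sign recovery at two groups of
10M+10F over 60 days with a +1.0 logit FF-only effect (50 replicates x 60
permutations); LRT null calibration at 400 simulated datasets of 60 dyads.
`scripts/acceptance.py` runs the full pipeline once at the two-group
demographic defaults with 200 permutations.

## Known limitations

- The beta family assumes a common precision phi across dyads; zero- or
  one-inflated and ordered-beta variants are out of scope.
- Contrast p-values use the normal approximation; with few individuals they
  are anti-conservative.
- Laplace accuracy degrades for large random-effect variances with few
  observations per individual; the quadrature evaluator is available for
  spot checks up to six latent dimensions.
- Separation in the occurrence models (small, dense datasets) produces the
  usual diverging logistic estimates with very large standard errors; fits
  are flagged, not regularized.
- The uniform day-conditional permutation treats all identified dyads as
  equally observable within a day; it does not condition on which members
  were focal. The degree-preserving scheme is provided as an alternative.
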