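# Methods

## Estimation model

Deaths at single ages x = 0…19 in a stratum (race group × sex × residence
× region) are modeled as `D_x ~ Poisson(P_x · h(x))`, with exposure `P_x`
approximated by the census headcount at the interview.  The log hazard is
written relationally against a standard schedule:

    log h(x) = log h_std(x) + B(x) α

`B` is the linear B-spline (hat-function) basis on knot ages
{0, 1, 5, 10, 15, 19}; each row of `B` sums to one, and `α_j` is the log
risk ratio relative to the standard at knot j.  The offsets maximize

    Q(α) = Σ_x [D_x (log h_std(x) + B_x α) − P_x h_std(x) e^{B_x α}]
           − k Σ_j (α_{j+1} − α_j)²

The first-difference ridge (default `k = 1`) penalizes curvature in the
risk-ratio function but not its level: a uniform shift of all offsets is
unpenalized, so the estimator is unbiased for proportional deviations from
the standard even at small exposures.  `Q` is strictly concave whenever
any deaths are observed (the Poisson term is concave; the penalty is
convex), so the maximizer is unique.

### Knot placement and penalty

The study population spans ages 0–19 only, so knots are dense in early
childhood (0, 1, 5) where mortality changes fastest, and sparser through
adolescence (10, 15, 19).  Both the knot set and `k` are configuration,
not constants: small strata benefit from larger `k`; `k = 0` with knots at
every age reproduces the saturated per-age MLE `D_x / P_x` exactly (a
tested identity).

### Fitting

Newton ascent from `α = 0` (the standard itself):

* gradient `Bᵀ(D − μ) − 2k SᵀS α`, with `μ_x = P_x h_std(x) e^{B_x α}` and
  `S` the first-difference matrix;
* negative Hessian `Bᵀ diag(μ) B + 2k SᵀS`, factorized by Cholesky — a
  factorization failure (possible at `k = 0` with deficient data) raises a
  numerical error advising a larger penalty;
* step-halving whenever a full step fails to increase `Q`;
* convergence when the largest offset change falls below 1e-8 (default),
  capped at 50 iterations with a warning and `converged = False`.

Ages with `P_x = 0` are dropped from the likelihood; their fitted rates
are still reported from the spline.  `D_x > 0` with `P_x = 0` is a data
error.  A stratum with **zero deaths at every age is skipped** by the
pipeline: the unpenalized level direction then has no likelihood maximum
(`Q` increases as all offsets go to −∞), so the level is not identifiable.

### Uncertainty

The covariance of `α̂` is the inverse negative Hessian at the optimum.
Pointwise intervals for log rates use the delta method,
`SE(x) = √(B_x Cov B_xᵀ)` and `CI = exp(log ĥ(x) ± 1.96·SE)`; a seeded
parametric bootstrap (`D*_x ~ Poisson(P_x ĥ_x)`, refit) is available as a
cross-check (`method="bootstrap"`).  Coverage of the analytic intervals is
verified by simulation: at exposure 5×10⁴ per age under known spline
offsets, mean pointwise coverage over 500 replicates falls in the 92–97%
band (the acceptance script recomputes this).

### Age-group probabilities

With constant hazard within each completed year,
`q_g = 1 − exp(−Σ_{x∈g} m_x)` for groups [0,1), [1,5), [5,10), [10,20);
values are reported per 1000 to one decimal, ratios to two decimals.  An
optional infant separation factor `a₀ = 0.1`
(`q₀ = m₀ / (1 + (1−a₀) m₀)`) is available for sensitivity; the default
keeps the constant-hazard form for all groups.  Because `q_g` is a
nonlinear functional of several correlated rates, its interval comes from
1000 seeded multivariate-normal draws of `α̂` pushed through the
rate-to-probability map (percentile bounds), not from a delta method.

## Attribution and tabulation

Deaths carry no color/race; each decedent is attributed the race of the
head of their household.  Household typologies 1–4 (any member / strict
majority / all members / head) decide Indigenous status; "more than half"
is strict (`> 0.5`), so exactly half is not a majority — the boundary the
definition leaves open is resolved toward the conservative side.  Typology
implications 3 ⇒ 2 ⇒ 1 and 3 ⇒ 4 hold for every household and are
property-tested.  If a household lacks a head flag, the oldest resident
(first record on ties) is designated head with a logged warning, keeping
attribution total on imperfect data.

The "yellow" category is excluded throughout (both self-declared and
attributed); the non-Indigenous group is the union of white, black and
brown.  The five major census regions are recombined into four, pooling
South and Southeast.  Exposure is the enumerated headcount; an optional
flag adds `D_x/2` back to exposure for sensitivity (decedents are not
enumerated), off by default.  Composition percentages round half away
from zero to one decimal, matching printed census tables.

## Standard schedule

Standards are sex-specific.  The bundled fixture is a Siler hazard
`a₁e^{−b₁x} + a₂ + a₃e^{b₃x}` with parameters chosen to resemble a
national 2010-era schedule over ages 0–19: male infant rate ≈ 0.016
falling steeply to ≈ 2×10⁻⁴ in late childhood and rising to ≈ 0.0016 at
19; the female schedule is lower throughout.  TOPALS is relational — any
plausible standard exercises the method — and a user-supplied single-year
life table (`age,mx`, ages 0–19) replaces the fixture via
`read_life_table`.  Files round-trip losslessly to 12 significant digits.

## Synthetic census generator

The generator emulates the study design, not Brazilian demography in
detail:

* **Strata** are sex × residence × region cells, each with its own race
  mix and household count.  Every member of a household takes the
  stratum's sex; since attribution and tabulation never cross sexes, the
  simplification is invisible downstream.
* **Households** draw a size from a configurable distribution (default
  mean ≈ 3.3, sizes 1–6), one head aged 20–80 uniform (heads never enter
  the 0–19 study population), and members aged 0–19 uniform (an
  `age_sampler` hook overrides this).  Members share the head's race with
  probability `homogeneity` (default 0.9), else redraw from the stratum
  mix — the single dial controlling how much the four typologies can
  disagree.  At `homogeneity = 1` every household is race-uniform and all
  typologies coincide exactly (tested).
* **Deaths** are Bernoulli per person with `p = 1 − e^{−m}` from true
  stratum × race schedules; the fitting model treats counts as Poisson.
  This mild mismatch (a person can die at most once) is intentional and
  vanishes at small m: for m ≤ 0.05 the mean-count discrepancy is below
  0.1%.  Decedents remain in the persons table, matching the use of
  census headcounts as exposure.  True schedules cover ages 0–19 only, so
  heads are not at risk within the simulated year.
* **Single-person-household censoring** (optional) deletes both the death
  and the household when a one-person household's resident dies — the
  household would not exist at interview time.  This reproduces the known
  undercount mechanism of retrospective household death questions.
* The bundled `example_config` scales Indigenous household shares by
  region and residence so the simulated Indigenous under-20 composition
  is ~74% rural with the regional gradient of the 2010 census frame, and
  sets Indigenous true rates to `indigenous_rate_ratio` (default 2.0)
  times the standard, rural rates 1.3× urban.

What the generator does **not** emulate: realistic household size/age
pyramids, fertility and migration, differential census coverage,
age-heaping, or race misclassification.  Passing tests therefore
demonstrate the estimator recovers known truth under the stated sampling
model — not that any particular real-world estimate is correct.

## Randomness and reproducibility

One integer seed drives a run.  The generator derives fixed per-stage
sub-streams (population, deaths) so stages are independently reproducible;
the analysis derives one interval-draw seed per fitted stratum from the
run seed.  Identical (config, seed) pairs produce byte-identical output
files.

## Problem sizes

Default test and demo scenarios use a few thousand households per stratum
(10⁵–10⁶ simulated persons at most); the coverage simulation uses 500
replicates at exposure 5×10⁴ per age; the parameter-recovery run uses
140,000 households (~5.6×10⁵ persons), giving ≥ 10⁴ exposure per single
age per race group.  These sizes were chosen so each property is measured
well inside its sampling noise.

## Known limitations

* Exposure is a headcount, not person-years; at national census scale the
  distinction is second-order for ages 0–19.
* The analytic CI relies on asymptotic normality of `α̂`; for strata with
  very few deaths the bootstrap alternative is more honest (and wider).
* Zero-death strata are reported as skipped rather than estimated; pooling
  (larger strata or a larger penalty) is the remedy.
* The comparison flag `ci_overlap` is interval overlap, not a formal test
  of rate equality.
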