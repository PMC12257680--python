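# Methods

`woolres` turns irregular longitudinal records of wool fibre diameter (FD,
measured every 5 mm along the staple by OFDA-type instrumentation) and body
weight (BW, weighed at shared flock occasions) into per-animal resilience
phenotypes, and estimates their genetic parameters with single-step animal
models.  This note describes each model, its assumptions, the tunable
parameters, and the numerical choices made where the design was open.

## 1. Standardization

Raw records are z-scored across animals within their flock-year group (FD)
or within flock-year x recording moment (BW), with the n-1 denominator.
Recording moments are recovered by gap clustering of the recorded ages
(a new occasion starts when the gap to the previous sorted age exceeds
7 days); the threshold matters only if two true occasions are closer than a
week.  A consequence worth knowing: per-occasion standardization removes
the cross-sectional mean of BW at every occasion, so the BW *group mean*
curve is close to flat and the weaning collapse is usually not detectable
on it — weaning-window analyses are most informative on FD, where
standardization is a single affine map per group and preserves curve shape.
Single-record occasions (a stray weighing date shared with no herd mate)
are dropped by the pipeline before standardizing.

## 2. Penalized B-spline smoothing

Each animal's standardized records `(t_j, y_j)` on `[0, L]` are fitted by
minimizing `sum_j (y_j - x(t_j))^2 + lambda ∫ x''(t)^2 dt` over B-spline
curves `x = c' phi(t)`.  Defaults: order 4 (cubic) for FD, order 3
(quadratic) for BW; interior knots at the 10 within-group deciles of the
pooled positions (type-7 empirical quantiles), plus extra BW knots at 30
and 60 days where lambs are not weighed between birth and weaning;
`lambda = 2500`; prediction grids of 1 mm (FD) and 10 days (BW).

Numerical choices:

- The curvature Gram matrix is exact (Gauss-Legendre per inter-knot
  interval, exact for the piecewise-polynomial integrand).
- The solve uses the stacked least-squares form `[Phi; sqrt(lambda) E]`
  with `R = E'E`, small penalty eigenvalues truncated to an exact null
  space.  This keeps the `lambda -> infinity` limit exactly on the
  ordinary-least-squares straight line and reproduces linear data to
  machine precision at any `lambda`.
- At `lambda = 0` a basis function unsupported by data makes the normal
  equations singular; this is raised as `SingularFitError`, never silently
  regularized.
- **Domain units.**  The penalty's strength depends on the units of `t`.
  On the staple-mm axis `lambda = 2500` leaves only ~4 effective df per FD
  curve — a straight-ish trend that cannot express a weaning check.  The
  staple is a time record (1 mm of staple is roughly 3 days of growth at
  typical sampling ages), and with the FD penalty acting on that
  growth-time axis in days the same `lambda` leaves ~7.7 effective df,
  which smooths measurement noise while keeping the short-term structure
  the indicators need.  The package therefore fits FD on the day axis
  (per-animal factor `sampling_age / staple_length`) while all grids and
  knots remain in mm.  BW is already on the day axis (~6.4 edf of ~13
  records).
- Group knots are defined on the group-mean domain length and rescaled
  proportionally into each animal's own domain, so every animal in a group
  shares one prediction grid (required by the alignment step); the residual
  linear time-scaling this introduces is part of the phase variation the
  next stage removes.

## 3. Elastic (SRVF) alignment

Within each flock-year group, phase variation is removed in the square root
velocity representation `q = sign(f') sqrt(|f'|)`.  Each animal's warp

    gamma* = argmin_gamma ||mu - (q o gamma) sqrt(gamma')||^2 + lambda R(gamma)

is found by dynamic programming, and the group Karcher mean `mu` is updated
as the cross-member average of aligned SRVFs, re-centred each iteration so
the mean warp is the identity; iteration stops when the objective change
falls below `tol` (default 1e-4 relative), and an iteration that would
increase the objective is rejected, so the recorded objective trajectory is
non-increasing by construction.

- Penalty: `R(gamma) = ||sqrt(gamma') - 1||^2`, the standard
  identity-deviation roughness in SRVF space.  `lambda = 0` is fully
  flexible; the sensitivity grid is {0, 0.2, 0.4, 0.6} with operating
  points 0.2 (FD) and 0.6 (BW).
- Curves are rescaled to `[0, 1]` internally (the SRVF scales by
  `sqrt(L)`, which keeps the data term and the penalty on the same footing
  across groups and series); warps are mapped back to physical units.
- DP lattice: full n x n grid; allowed steps are coprime `(di, dj)` with
  components up to 8 and slope within `[1/5, 5]`; edge costs use `2*di`
  midpoint samples; ties break toward the diagonal (slope closest to 1),
  so large-`lambda` alignments settle on the identity.  The DP core is
  numba-jitted with a pure-Python fallback.
- On 150 warped copies of a known template the procedure removes >95% of
  each member's SRVF distance to the mean at `lambda = 0` and recovers the
  template's amplitude within ~4%; the residual is the DP's slope
  quantization plus a small common-phase drift of the mean, both of which
  shrink with grid resolution.

## 4. Resilience indicators

Deviations are `x_i = aligned individual value - group mean value` on the
prediction grid.  General indicators per animal and series:

- `Lnvar`: natural log of the (n-1)-denominator variance.  The printed
  skewness formula in the source literature omits its exponent; the
  package implements the standard third standardized moment
  (`Skewness = mean(((x - xbar)/s)^3)` with the n-1 sd).
- `Auto`: lag-1 autocorrelation, n-1 cross products over n squared terms.
- `ABS`: mean absolute successive difference.

Weaning indicators are defined on the flock-year window: the first local
minimum of the group mean after the weaning anchor (BW: mean weaning age;
FD: mean weaning age mapped to staple position proportionally, with
position 0 at the birth end of the staple), then the next local maximum.
Extrema are first-difference sign changes; a window qualifies only if both
the drop from the anchor and the rise to the recovery crest exceed 0.1
group-SD of the mean curve (configurable prominence), and the minimum must
fall within 40% of the domain after the anchor.  Undetected flock-years
are excluded from the weaning traits (missing, never zero-filled) — on
simulated cohorts a few percent of dip-carrying flock-years are genuinely
undetectable because the recovery crest is masked by the seasonal decline,
which mirrors how real flock-years without a clear weaning challenge are
excluded.  `ROC_response` and `ROC_recovery` are the animal's own rates of
change over the group-level window positions; `ABC` is the trapezoid area
between the animal's curve and the group mean over `[t_w, t_max]`
(negative = stronger response / slower recovery).  A single-pass 3-SD
filter per trait per flock-year flags outliers.

## 5. Genetic parameters

Univariate model: `y = Xb + Z1 a + Z2 m + e`, with birth-rearing type
(3 levels) and contemporary group (flock-year x sex) as fixed effects,
`var(a) = H sigma_a2`, `var(m) = I sigma_m2` (maternal permanent
environmental effect, one level per dam; unknown dams get singleton
levels), `var(e) = I sigma_e2`.  Heritability is
`sigma_a2 / (sigma_a2 + sigma_m2 + sigma_e2)` with a delta-method SE.
Bivariate models put unstructured 2x2 matrices on each component;
`r_g = sigma_a12 / sqrt(sigma_a1^2 sigma_a2^2)`, `r_p` from summed
components, significance by the |estimate| > 2 SE rule.

- `A` by the tabular method with inbreeding; `G` by VanRaden method 1 with
  observed allele frequencies; `H` from
  `G_w = alpha G + (1 - alpha) A22` (alpha = 0.95) via the standard
  single-step construction, reducing exactly to `A` with no genotypes.
- REML works on the phenotype covariance `V = sigma_a2 H_obs + sigma_m2
  Z2 Z2' + sigma_e2 I`, which needs only the phenotyped-animal submatrix
  of `H`.  All likelihood quantities decompose over connected components
  of V's sparsity graph, so family designs cost little even at thousands
  of records; a fully connected cohort falls back to one dense block
  (practical to n of a few thousand).
- Optimizer: 3 EM warm-up multiplicative updates, then average-information
  steps with step halving (a step is accepted only if the restricted
  log-likelihood does not decrease), an EM fallback direction when the AI
  step fails, variance floors at 1e-8, covariances bent inside the PSD
  cone, and an active set for parameters at the floor.  Convergence:
  relative log-likelihood change < 1e-8 with relative parameter change
  < 1e-6 (or three consecutive stalled iterations).  SEs come from the
  inverse AI matrix.
- On balanced half-sib designs the estimates agree with the closed-form
  ANOVA estimators to ~1e-12; across 20 simulated replicates at n = 3000
  (true h2 = 0.10, maternal 0.05) the mean estimate is unbiased to ~0.01
  and nominal 2-SE coverage holds.

## 6. Synthetic cohort generator

The generator emulates the study structure end to end: 41 flock-year
groups of ~150 animals by default (tests and the acceptance script run
scaled-down cohorts of 8-12 groups x 40-60 animals and family designs of
n = 3000 records, stated with each result), three-generation pedigrees
with half of each group's sires drawn from a shared pool, FD at 5 mm steps
with 10-27 records per animal, BW at shared occasions (birth, then ~18-day
intervals from weaning) with 5-20 records, and weaning at mean day 90
(range 62-119).

Each record is built as: group template (Gompertz growth for BW; a gentle
seasonal trend for FD peaking ~20 days after birth — a single lambing
season, so the phase is common across flock-years up to small jitter) +
disturbances x the animal's susceptibility + measurement noise, observed
through a smooth random monotone time warp (normalized integral of a
log-Gaussian process; `phase_sd` controls its magnitude).  Disturbances
are a C1 weaning dip (depth 1.5 group-SD, 18-day collapse, 35-day recovery
to 90% of the drop) plus Poisson transient bumps (1.2 per 100 days,
amplitude 0.7 SD, mostly negative).  Susceptibility is
`exp(u - var(u)/2)` with `u = a + m + e` simulated from the pedigree at
h2 = 0.1 and maternal 0.05 — it is itself a heritable trait, so indicator
heritability recovery is testable against a known truth.  Mendelian
sampling uses F = 0 (the generated pedigrees are non-inbred).  All
randomness flows from one seed through fixed per-module streams; a fixed
seed reproduces every artifact bitwise.

What the generator does *not* emulate: linkage disequilibrium, selection
across generations, climate covariates, genotype-environment interaction,
multi-year repeated measures, and measurement-error structure specific to
OFDA instruments.  Passing tests therefore demonstrate that the pipeline
recovers the structure this generator embeds — heritable disturbance
susceptibility expressed through curve variability — not that real wool or
weight data carry the same signal.

## 7. Known limitations

- Dense linear algebra throughout: pedigrees and cohorts beyond ~10,000
  animals need sparse MME machinery this package does not provide.
- The DP warp is exact only on its lattice; warps needing slopes outside
  `[1/5, 5]` are truncated.
- BW weaning traits inherit the flat-group-mean problem of per-occasion
  standardization (Section 1).
- Equivalence with any particular external alignment software is not
  claimed; what the package guarantees are the contracts (warp validity,
  objective monotonicity, template recovery) checked by its test suite.
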