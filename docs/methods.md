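# Methods

## The measurement model

`testmat` implements a multidimensional 3PL item response model with
person-specific random testlet effects.  For person *j* with ability vector
**θ**\_j (length *P*), an item with loading vector **a**, difficulty *b*,
pseudo-guessing *c*, nested in testlet *d*:

    P(U = 1) = c + (1 − c) · logistic( a′(θ_j − b·1 − γ_jd·1) )

The difficulty and the testlet effect are multiplied by the ones vector, so
they enter every dimension the item loads on; with simple structure (one
nonzero loading) the exponent reduces to `a_p (θ_p − b − γ_d)`.  Setting all
γ to zero recovers the plain multidimensional 3PL (MIRT); restricting
loadings to 0/1 and c = 0 gives the multidimensional Rasch testlet model
used throughout the simulation study.

Assumptions: each item belongs to exactly one testlet; testlet effects are
mutually independent, independent of **θ**, and normal with mean 0 and a
testlet-specific variance σ²\_d.  That variance is the model's index of
local item dependence (LID): residual correlation between items of a
testlet after conditioning on ability, which inflates apparent information
when ignored.

Exponent arguments are clipped to ±35 before exponentiation; this preserves
monotonicity and keeps probabilities strictly inside (c, 1) at extreme
abilities.  Items with an all-zero loading vector are permitted (constant
probability c + (1−c)/2) with a warning; they are useful as null fixtures.

## Information and D-optimal testlet selection

Fisher information in any coordinate pair (x, y) of the stacked
(θ, γ₁…γ_v) parameter is `(∂P/∂x)(∂P/∂y) / (P·Q)` summed over answered
items.  Because γ enters the exponent negatively, cross entries between a
testlet effect and an ability carry the signed product (negative for
positively loading items); the testlet block is diagonal since items of
different testlets share no effect.  The assembled matrix equals the
negative expected Hessian of the log likelihood, which the test suite
verifies against a finite-difference oracle.

As testlets are answered, the prior covariance over the stacked parameter
grows by one row/column per testlet — the ability block Φ in the upper-left
corner, effect variances on the remaining diagonal, zero elsewhere — and the
information matrix grows correspondingly.  A testlet-effect variance of
exactly zero is floored at 1e−6 when the prior is inverted, so the
machinery stays defined in the no-LID condition where it must mimic MIRT.

The next testlet maximises `det(Φ_v⁻¹ + I_v(θ̂, γ̂) + I_v(θ̂, candidate))`.
Candidate testlets contribute only ability-block information, evaluated at
their effect's prior expectation of zero (their effect dimension is not yet
instantiated), so candidate scoring is identical under the testlet model
and plain MIRT.  Since the candidate touches only the P×P ability block,
the determinant factorises as `det(M) · det(I_P + Δ G)` with
`G = (M⁻¹)[:P,:P]`; the engine ranks candidates by `log det(I_P + Δ G)`,
a strictly monotone transform of the raw determinant.  Ties break to the
candidate earliest in pool order (lowest id in the generated pools).
Candidate testlet information is the sum of its items' informations by
default; a mean variant is available for pools of mixed testlet size.

## Estimation

**Provisional (within-test): Bayes modal.**  The posterior mode of the
stacked (θ, γ) vector under the expanded normal prior is found by Fisher
scoring — `x ← x + (Φ_v⁻¹ + I_v)⁻¹ · ∇log posterior` — with step halving
and warm starts from the previous testlet.  The scoring matrix is positive
definite by construction, which keeps iterations stable even for 3PL
items.  Convergence tolerance 1e−4 on the step, cap 100 iterations;
non-convergence during an administration is recorded on the person's
record and the last iterate is kept.  During simulated administrations
the generating item parameters, Φ and the effect variances populate the
prior (the usual known-parameter assumption of operational adaptive
testing); a configurable override exists.

**Final scaling: Metropolis-within-Gibbs.**  After administration the
complete response set is re-scaled by MCMC with item parameters fixed:

* θ_j: joint P-dimensional random-walk Metropolis per person, all persons
  in parallel;
* γ_jd: independence Metropolis per answered testlet slot — given θ the
  slots are conditionally independent, so all N×v effects update in one
  vectorised sweep.  Each effect is informed by only a few items, which
  makes random-walk updates mix slowly and lets the variance chains chase
  the effect dispersion far past equilibrium before recovering; instead,
  each sweep locates the 1-D conditional mode per slot (Newton from zero,
  so the proposal depends only on θ and σ² and the kernel is exactly
  reversible) and proposes from a normal at the mode with
  curvature-matched, slightly inflated width.  Acceptance sits near 0.9
  and successive draws are almost independent;
* Φ_θ: conjugate inverse-Wishart full conditional (prior: identity scale,
  9 degrees of freedom — the printed degrees of freedom with a proper,
  weakly informative scale);
* σ²\_d: conjugate inverse-Gamma full conditional (prior shape = scale =
  0.001, a vague proper choice), followed by an interweaved rescaling move:
  random-walk Metropolis on log σ_d in the ancillary parameterisation
  (γ = σ·γ̃ with γ̃ held fixed), with per-testlet proposal scales
  ∝ 1/√(exposure).  Effects informed by only a handful of items leave the
  sufficient-parameterisation Gibbs step little room to move the
  variances; the interweaving restores that mobility at the cost of one
  extra likelihood sweep per iteration.

The ability and log-variance proposal scales adapt toward a 0.2–0.5
acceptance rate during the minimum burn-in and are frozen afterwards; the
effect proposals need no adaptation (independence proposals track the
conditional posterior by construction).  γ chains start dispersed at the initial
variance rather than at zero (zero-start collapses the conjugate variance
draw early, and the chain recovers slowly).  The variance prior support is
truncated to [1e−8, 1e4]: under the vague prior a variance informed by one
or two persons is nearly flat in log σ and would otherwise random-walk to
overflow; the bounds are orders of magnitude beyond substantively possible
values.

**Burn-in control.**  Burn-in extends in blocks of 500 iterations until the
Geweke criterion passes on the monitored parameters or a cap is reached
(default 5,000 in the scaled-down profile).  Monitored: every testlet
variance with exposure ≥ 20 persons (on the log scale — the conjugate
draws are heavy-tailed), the ability-covariance entries, and 10 sentinel
abilities.  Each score compares the first 10% with the last 50% of the
trailing half-window, with segment-mean variances from Geyer's
initial-positive-sequence estimator (naive variances understate
autocorrelation and inflate the scores).  With ~70 monitored parameters,
demanding every score below 1.96 has a familywise false-alarm rate near
one, so convergence is declared when at most 5% of scores exceed 1.96
(the nominal rate) or when no score exceeds the Bonferroni-corrected
familywise threshold.  Hitting the cap emits a warning and the results are
still returned, with the full score set in the convergence report.

Point estimates are means over the retained window (default the last 500
iterations): EAP abilities, per-testlet posterior-mean variances, and the
posterior-mean ability covariance.

**Variance summary.**  The study-level "estimated testlet effect variance"
averages the per-testlet posterior means weighted by exposure, excluding
testlets answered by fewer than 20 persons, whose posteriors are dominated
by small-sample skew.  Under uniform exposure — random administration, or
any design at full scale — this reduces to the plain mean across testlets;
at reduced scale it stabilises the summary under the very uneven exposure
that adaptive selection produces.

**MML difficulty calibration.**  For the shrinkage analysis, difficulties
are re-estimated under plain MIRT by marginal maximum likelihood: because
each item loads on one dimension whose marginal ability distribution is
standard normal, each dimension is calibrated as a unidimensional model by
EM with 21-point Gauss–Hermite quadrature (vectorised E-step; four Newton
updates per item per M-step; convergence at 1e−5 on the difficulties).
Items with all-0/all-1 response vectors are flagged and pinned at ±8.

## The simulation study

The generator reproduces a three-dimensional large-scale-assessment
setting: abilities MVN with unit variances and latent correlations 0.80;
324 Rasch items (108 per dimension, simple structure) with difficulties
uniform on (−4, 4); testlets formed within dimension by chunking items in
difficulty rank order into groups of 3, 6 or 9 (so testlet-mates share a
dimension and are homogeneous in difficulty); testlet effects i.i.d.
normal with variance 0, 0.5, 1.0 or 1.5.  One pool is generated per study
and shared by all conditions; every administration runs 54 items (18, 9 or
6 testlets).  Responses are always generated under the testlet model; the
scoring model (testlet vs. plain MIRT) and the selection rule (D-optimal
vs. random-without-replacement) are the experimental factors.

For plain-MIRT scoring the generating difficulties are first multiplied by
a condition-specific shrinkage factor: the OLS slope (with intercept,
pooling all 324 items) of MML-recalibrated difficulties on generating
difficulties, computed from a full N=5,000 response matrix.  The
logit-probit closed form `(1 + σ²/1.7²)^(−1/2)` reproduces these factors to
within 0.02 and serves as an independent check.

Ability recovery is summarised by the dimension-averaged mean squared
error `MSE = (1/P) Σ_p (1/N) Σ_j (θ̂_jp − θ_jp)²` of the EAP estimates,
with across-replication standard deviations as precision measures.

**Scale of the shipped profile.**  The default study profile runs 500
persons and 2 replications per cell with the burn-in cap at 5,000 and 500
retained iterations; the shrinkage calibration keeps the full N=5,000.
The reproduction script (`scripts/acceptance.py`) runs its targeted cells
at 1,000 persons — variance-component posteriors are exposure-limited, so
the headline quantities get the larger sample — and finishes in well under
twenty minutes of CPU time.  Random-number streams derive deterministically
from one root seed (per-condition, per-replication child streams), so
every table is bit-reproducible.

## What reduced scale does and does not show

Several finite-sample effects are visible at 500–1,000 persons that vanish
at the published scale of 5,000 — all confirmed against an exact
one-dimensional quadrature posterior (the oracle fixes abilities at truth
and integrates each testlet's effects numerically), so they are properties
of the exact posterior under the vague prior, not of the sampler:

* With 54 answered items per person the per-testlet exposure averages
  N/6 persons.  For a true variance of zero, the posterior mean stays
  visibly positive (≈ 0.09–0.16 at N = 500, depending on items per
  effect).
* For small positive variances with small testlets the pull goes the other
  way and is strongest: at σ² = 0.5 with 3-item testlets under random
  administration, the exact posterior mean is ≈ 0.41 at 167 persons per
  testlet (three near-flat Bernoulli likelihood contributions per effect
  leave the near-1/σ² prior substantial influence).  Adaptive selection
  concentrates exposure, so its exposure-weighted summaries sit closer to
  truth.  At σ² = 1.0 the pull is ≈ −5–10%; at 1.5 it is negligible.

The generator also idealises real assessments: item parameters are exactly
known, guessing is absent in the study conditions, testlets are perfectly
homogeneous in difficulty, and there is no exposure control, content
balancing, position effect or motivation drift.  Passing tests therefore
demonstrate the engine's internal correctness and the relative ordering of
designs under the model, not performance on any operational item pool.

## Known limitations

* Polytomous items and the bi-factor parameterisation with free testlet
  slopes are out of scope; within-item multidimensional testlets are
  supported only through the literal ones-vector form of the model.
* The sampler estimates the ability covariance by default (a switch fixes
  it); identification rests on the fixed item parameters.
* Variable-length termination, exposure control and alternative selection
  criteria (Kullback–Leibler, mutual information, trace-based rules) are
  not implemented.
* Monte-Carlo standard errors reported for EAPs are naive (retained-window
  standard deviations); they ignore residual autocorrelation.
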