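# Methods

## Model

`jointnet` treats a pair of directed binary networks on a shared node set
as a sample of iid dyads.  Each ordered cell (i, j), i ≠ j, carries the
linkage state x = (A_ij, A_ji, B_ij, B_ji); the 16-cell contingency
vector of these states is the sufficient statistic.  The model family is
the exponential tilting family anchored at the mean-field independence
null: every node pair is exchangeable, each of the four edge indicators
has a constant rate, and association structure enters only through
constraint functions on the 16 states.  The null deliberately ignores
node covariates (sex, kinship, rank); it is the maximum-entropy
distribution given the two densities alone, which makes every later
constraint interpretable as association *beyond* density.

Accommodating a constraint f means replacing the current model p by
p′ ∝ p·e^{λf} with λ chosen so the model mean of f equals its empirical
mean.  p′ is the I-projection of p onto the moment constraint: the
closest distribution in KL divergence, hence the one adding no structure
beyond what f demands (verified in the test suite against a generic
constrained KL minimizer on the simplex).  Fitting is *sequential and
greedy*: earlier multipliers are frozen and each accommodated model
becomes the next null.  This matches the published iterative procedure
the package reproduces, and makes each λ interpretable against the model
state at its own step; a cyclic-coordinate `joint_refit` that matches
all moments simultaneously is provided as an explicitly non-standard
alternative.

## Counting conventions

The published worked example never states its counting convention; the
package's default (`paper-n2`) was chosen because it reproduces the
published census arithmetic exactly: all n² ordered cells are tallied,
the n diagonal cells into the all-zero state; class reports give
asymmetric classes in one orientation (= unordered dyads in that
configuration) and symmetric classes in full ordered count.  On the
packaged census this yields a 16-state total of 5929 = 77², implied
directed grooming edges 187, and the published expected counts to ±0.01.
Principled alternatives (`offdiag`, `dyad`) are provided for reuse; the
generator and recovery experiments use `offdiag` so the diagonal's
artificial all-zero mass never enters a stochastic fit.

Marginal rates are estimated from the tally's implied edge totals over
its total cells, not from externally supplied densities.  On the packaged
census this gives p_B = 645/5929 ≈ 0.10879 although the source prints
0.10896 (one aggression edge of discrepancy in the source's own numbers);
the tally-derived rate reproduces all published expected counts, so the
validation output flags rather than resolves the inconsistency.

## Constraint functions

- f₁, f₂ (reciprocity): (x1−p)(x2−p) per network, centered at the current
  model's marginal rate.  Exactly mean-zero while the two directions are
  independent, so each is perpendicular to the model it amends.
- f₃ (opposition): (x1−x2)(x4−x3) ∈ {−1, 0, +1}, +1 on opposite-direction
  one-way dyads, −1 on same-direction ones.  Mean-zero under any
  mirror-symmetric model with independent A/B blocks.  Its exact
  published form is not recoverable from the source text; this
  reconstruction is validated by the tilt identity count(1001)/count(1010)
  = e^{2λ} against the published post-f₃ column (26.06/8.06 at λ = 0.5868).
- f₄ (presence covariance): (max(x1,x2)−a)(max(x3,x4)−b), positive when
  both or neither behavior is present on the dyad.  Two centering
  policies ship.  The principled default draws a and b from the current
  model's any-A-edge / any-B-edge probabilities.  Back-solving the
  published final column instead identifies a as the model any-A rate but
  b as the *empirical one-way-B-only* cell frequency (≈ 0.1467); that
  pairing is provided as `paper-table-1-compat` and is what exact
  reproduction uses.  The two policies tilt in slightly different
  directions (only purely additive recentering is absorbed by the
  partition function); on the packaged census the principled default
  reaches a final total χ² of 16.79 and the compat policy 18.93, both
  under the 99% critical value 21.666.

Constraint mean-zero deviations are recorded per step, not enforced:
additive constants cancel between the partition function and the moment
constraint, so re-centering cannot change a fit, but the deviation is a
useful perpendicularity diagnostic (f₂ and f₃ are exactly perpendicular
at their steps; f₄'s deviation is a small residual covariance).

## Numerics

Tilts are computed in log space with max-subtraction, so arbitrarily
large multipliers cannot overflow.  λ is solved by bracketed Brent
root-finding on λ ↦ E_tilt[f] − target, bracket expanded geometrically
from [−1, 1]; the map is strictly increasing (its derivative is the tilt
variance of f), so the root is unique; residual tolerance 1e−12 on λ,
verified to 1e−8 on the moment.  Targets outside the open interval
(min f, max f) over the model support, and constraints constant on the
support, are rejected with the attainable range in the error.
Probabilities are never floored: structurally empty classes (e.g. the
all-four-edges class in sparse data) legitimately carry near-zero mass,
and a zero observed with zero expected cell is excluded from χ² with a
warning, while zero expected with positive observed is an error.

Degrees of freedom default to 9 (10 classes minus 1) and are *not*
reduced for fitted constraints, following the reproduced procedure; a
log warning notes the unadjusted df when a caller changes it.  The
stopping level is a parameter (default 0.99; the reproduced trajectory's
final 18.93 sits between the 95% value 16.919 and the 99% value 21.666,
so at the 95% level a fifth constraint would be required).

## Synthetic data

The generator samples the model family itself: an independence null at
configured rates, optionally tilted by (constraint, λ) pairs, collapsed
to the 10-class dyad distribution (2p(rep) for asymmetric classes), then
one multinomial draw per unordered dyad with a fair-coin orientation for
asymmetric classes.  One seeded `numpy` Generator per experiment; the
seed is echoed in every report and manifest.  What it emulates: iid
mirror-symmetric dyads — exactly the model's world.  What it does not:
degree heterogeneity, transitivity, covariate structure, or any
across-dyad dependence.  Passing recovery tests therefore demonstrate
the estimator's consistency under the model's own assumptions, not
robustness to real-network violations of them.

Recovery experiments refit with constraints rebuilt against *estimated*
marginals, so recovered multipliers carry a small finite-sample
re-centering bias in addition to multinomial noise; at 500 nodes
(≈ 1.25×10⁵ dyads) the mean absolute error on a reciprocity multiplier
of 1.0 is ≈ 0.04 over the fixed test seeds, comfortably within the 0.15
the tests assert.  Problem sizes in the suite (n = 250–500, 3 seeds per
experiment) keep the full suite under ten seconds while leaving
Monte-Carlo error well below the asserted tolerances.

## Known limitations

- Two networks per joint encoding; multi-network systems are analyzed
  pairwise.
- Binary edges only; weights in input files are binarized with a warning.
- The mean-field null ignores node covariates and degree heterogeneity,
  so fitted multipliers conflate genuine behavioral coupling with any
  shared covariate structure.
- Constraint choice is manual (or user-supplied 16-value functions);
  there is no automatic constraint discovery.
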