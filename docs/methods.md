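# Methods

`trialadapt` addresses one question in adaptive clinical-trial design: once
the decision has been made to shrink a running two-arm trial by a given
number of participants, *which* participants should stop contributing data?
It does not decide *when* or *by how much* to shrink — those belong to
complementary sample-size re-estimation machinery.

## Stratification by blinding questionnaire

Blinding is never perfect: participants form beliefs about their assignment,
and those beliefs feed back into measured outcomes through expectation
effects.  The analysis framework adopted here therefore stratifies each arm
by the response to a periodically administered blinding questionnaire
(believes-control / uncertain / believes-treatment), yielding six sub-groups
G_C−, G_C0, G_C+, G_T−, G_T0, G_T+.  Only *matched* sub-groups — control and
treatment strata sharing a questionnaire response — are compared, so that
expectation effects are held constant within each comparison.

## Outcome model and marginal kernels

Within a sub-group, transformed outcomes x_i are modelled as i.i.d.
N(m, σ²) with improper uniform priors on m ∈ ℝ and σ ∈ (0, ∞).  (The `log`
transform maps positive, log-normally distributed trial variables into this
domain; outcomes that are already additive — such as the simulator's — enter
with the `identity` transform.)  Marginalizing (m, σ) against a test point x
gives a kernel proportional to c(x)^{−(n−1)/2}, where c(x) is the residual
of completing the square in m:

    (x−m)² + Σᵢ(xᵢ−m)² ≡ (am+b)² + c,
    a = √(n+1),  b = −(x+s₁)/√(n+1),
    c(x) = [n(x − x̄)² + (n+1)·SS]/(n+1),

with s₁ = Σxᵢ, SS = Σ(xᵢ−x̄)².  The exponent (n−1)/2 is fixed by the
σ-integration *after* the Gaussian integral over m has contributed its
factor σ; the test suite pins it against a brute-force two-dimensional
quadrature of the raw (m, σ) integral.  Normalized over x the kernel is
exactly a location-scale Student-t:

    df = n − 2,  loc = x̄,  scale² = (n+1)·SS / (n(n−2)).

This is proper only for n ≥ 3.  With only two observations the kernel has
1/x tails and no finite normalization, so every normalized quantity in the
package (ρ*, sensitivities, posteriors) requires at least three
observations per sub-group; the configurable eligibility floor
`min_subgroup_size` is therefore effectively max(its value, 3).

## The superiority functional ρ*

For a matched pair, ρ* is the posterior-marginalized probability that a
treatment outcome exceeds a control outcome,

    ρ* = P(X_t > X_c) = ∫ f_t(x) F_c(x) dx,

under the two independent predictive t distributions.  The implementation
restores the normalization constants dropped in unnormalized derivations —
only a normalized probability is comparable across sub-groups of different
sizes.  The integral is evaluated by Gauss–Legendre quadrature after the
tangent substitution x = center + scale·tan θ (center and scale pooled from
the pair), which compresses the real line and tames the polynomial t tails;
the order doubles adaptively from 129 to at most 2049 nodes until two
successive estimates agree to 1e−6 relative / 1e−8 absolute.  An exact
sampler of the same posterior (1/σ² ~ Gamma((n−2)/2, SS/2), m|σ ~
N(x̄, σ²/n), then one predictive draw) serves as the independent oracle.

The interface admits other distance functionals between the two posterior
predictives as plug-ins; only the superiority probability is shipped.

## Expected sensitivity to sub-group size

Ranking sub-groups for removal needs ∂ρ*/∂n for each side of each pair.
Enumerating actual n−1-subsets is combinatorial, so the derivative is taken
of the *expected* functional form: a side's sufficient statistics (n, s₁,
s₂) are continued to real ν as (ν, ν·m₁, ν·m₂) with the per-datum means m₁,
m₂ held fixed.  The continued kernel remains Student-t with df = ν−2 and
scale² = (ν+1)(m₂−m₁²)/(ν−2), so ρ̄*(ν) is smooth and differentiable.

Two interchangeable methods are provided:

* **finite_difference** (normative): central difference with step h = 0.1
  participants, falling back to a second-order one-sided difference when
  ν − h would leave the proper region.  Both evaluations share one fixed
  801-node quadrature rule so node-placement error cancels in the
  difference.
* **analytic**: differentiation of the normalized kernel under the integral
  sign; d log f/dν collects digamma and logarithm terms (the same ln-σ
  device that appears when the σ-marginalized kernel is differentiated in
  n).  The normalization's derivative is included.  The two methods agree to
  ~1e−6 relative on well-conditioned pairs; the test suite enforces 5%.

## The removal policies

The **proposed** policy is sequential: at each removal, stratify the active
cohort, compute both sides' sensitivities for every eligible pair, and
remove a uniformly random member of the sub-group with the smallest
|E[∂ρ*/∂n]| — within a sub-group outcomes are exchangeable, so the victim
choice carries no information.  Magnitude, not the signed value, is
compared ("smallest change" is directionless); signed values are logged.
Ties break toward the larger sub-group, then by a seeded uniform draw.
Sensitivities are recomputed from scratch after every removal, since they
depend on the current sizes.  The **random** baseline removes uniformly
from the whole active cohort.

## Posterior of the differential effect

The final analysis computes the posterior of δ = m_t − m_c per eligible
pair (each mean's posterior is t with df = n−2, scale² = SS/(n(n−2)); the
pair density is their numerical convolution on a common grid) and combines
pairs as a normalized mixture, weighted by pair size n_c + n_t by default
(uniform weights or a custom callable are accepted — the aggregation across
matched pairs is a genuinely open design choice, and size weighting
preserves total-information ordering).  The grid holds 2001 points spanning
the pair centers ± 6 combined posterior scales and widens automatically if
more than 1e−4 of mass falls outside.  The MAP estimate is the grid argmax
with ties broken toward the smaller δ.

## The trial simulator

The synthetic cohort emulates a 180-participant trial (90 per arm) over
k_max = 100 steps.  Effects accumulate as e(k+1) = e(k) + w(k+1)·e^{−(k+1)/10}
with w ~ N(0.02, 0.05) under treatment and N(0, 0.05) under control (second
parameter read as a standard deviation; the config flag
`noise_scale_is_sd=False` reproduces the variance reading).  The expected
differential converges to 0.02·e^{−0.1}/(1−e^{−0.1}) ≈ 0.19.  Beliefs start
at (−1 ×8, 0 ×73, +1 ×9) per arm, drift by φ·e(k+1) plus N(0, 0.005) noise,
and are thresholded at the closed interval [−1, 1] into the three
questionnaire tiers.  φ (outcome perceptibility) defaults to 0.01.

Noise is pre-drawn per participant from substreams spawned off the master
seed in id order: a participant's trajectory is identical regardless of
iteration order or of removals elsewhere, which is what makes the paired
policy comparison exact.  Setting all noise scales to zero makes the
recursion deterministic and equal to the closed-form damped partial sums —
zero scales are explicitly permitted for this reason.

What the simulator does *not* model: dropout for non-statistical reasons,
covariates, more than two arms, five-tier questionnaires, or any feedback
from outcomes to treatment administration.  Passing experiments on this
generator show that the machinery behaves as designed under its own model
assumptions; they do not certify performance on real trial data.

## Experiments and what they show

Experiments pair replicates: both policies consume the identical simulated
trajectories (same per-replicate simulation seed) and diverge only at
removal, so across-replicate comparisons isolate the selection rule.  The
headline statistic is 100·(1 − sd_proposed/sd_random) of the MAP estimates
across replicates.

Designs 1–4 remove once (70 at k=50; 50 at k ∈ {30,50,70}; n ∈ {30,50,70}
at k=50; φ ∈ {0.005,0.01,0.02}) and keep pre-removal data in the final
analysis: a removed participant contributes the outcome and the
questionnaire response observed at their removal step (their last observed
state).  Design 5 removes one participant per step for 120 steps of a
k_max = 150 trial and *discards* removed participants' data entirely,
tracking the MAP estimate and the six sub-group sizes per step.  The
horizon and start of design 5 are package choices (the sequential design is
an analytical probe, not a realistic protocol).

A structural observation, documented here because it bounds what the
policy comparison can show: when pre-removal data is retained and each
participant enters the final analysis through a single last-observed
outcome, removal changes neither the number of analyzed outcomes nor (up to
freezing maturity and tier) their values, so *any* selection rule perturbs
the final estimate only marginally relative to the irreducible
cohort-sampling noise of the estimand (≈ 0.106·√(2/90) ≈ 0.016 in outcome
units at the shipped settings, i.e. ≈ 8% of the 0.19 differential).  The
across-replicate sd of both policies is consequently dominated by that
shared noise floor.  In the discard-data sequential design the removal
policy genuinely changes the information content: the informed policy
demonstrably preserves the small matched pairs that random removal erodes,
but because the minimal-sensitivity rule concentrates removals in the
largest — and most informative — pair, its late-trial tracking of the
ground truth is not better than random's under this generative model.

## Numerical choices and problem sizes

* Quadrature: adaptive 129→2049 Gauss–Legendre nodes for ρ* (tolerances
  1e−6 rel / 1e−8 abs); fixed 801 nodes inside sensitivity differences;
  513-node inner rule in posterior convolutions.
* Posterior grid: 2001 points (801 in the per-step sequential analysis,
  where the posterior is recomputed 150 times per replicate).
* Replication: the shipped designs default to 100 replicates; the test
  suite runs the baseline single-removal condition at 60 replicates (its
  accuracy clause compares a replicate mean against a 1% bound, and 60
  replicates keep that mean's standard error below the bound), the
  parameter sweeps at 30, and the sequential design at 10; the
  reproduction script runs 100 replicates for the baseline condition and
  60 for the sweeps.
* Degenerate inputs: zero-variance sub-groups and sub-groups below the
  eligibility floor are excluded with a warning; an analysis with no
  eligible pair raises a distinct error and is counted as a failed
  replicate.

## Known limitations

* The flat prior on σ (rather than Jeffreys 1/σ) follows the derivation the
  package implements; it costs one degree of freedom (df = n−2) and raises
  the eligibility floor to three observations.
* The expected-sensitivity continuation holds per-datum means fixed; it
  does not capture the change in *which* member is removed (within-sub-group
  exchangeability makes this exact in expectation only).
* MAP estimates are grid-quantized; sub-grid interpolation is deliberately
  avoided to keep the tie rule exact.
* The policy comparison under kept pre-removal data is noise-floor limited,
  as discussed above.
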