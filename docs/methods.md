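# Methods

## Model

A monitored surgical process produces, per patient, an integer risk
score s ∈ {0, …, n} (n = 71 for the Parsonnet system) and a binary
30-day outcome y.  Two components define the monitoring problem:

* **Risk model.**  logit π(s) = b₀ + b₁·s.  The shipped default
  (b₀ = −3.6798, b₁ = 0.0768) is the Phase-I maximum-likelihood fit of
  the classic cardiac-surgery setting; `fit_risk_model` re-estimates it
  from data via IRLS (statsmodels).  A change in surgical performance
  multiplies the odds of death by Q*: π*(s)/(1−π*(s)) = Q*·π(s)/(1−π(s)).
* **Patient mix.**  The distribution of s.  Three parametric families:
  beta-binomial(n, α, β) (discrete, bounded — the natural fit for an
  integer score), the beta(α, β) distribution discretized into n+1
  equal-width cells of [0, 1], and the continuous beta(α, β).  The
  continuous variable x maps to the score scale as s = n·x.  Fitting
  uses the method of moments: the beta fit on interval-midpoint
  rescaled scores (s+½)/(n+1), the beta-binomial fit on raw scores.
  Inadmissible moments (zero variance, under-dispersion) raise an
  error rather than being clipped, so data problems surface instead of
  disappearing into a silently truncated parameter.

The RA CUSUM increment for chart design odds ratio Q_A (null Q₀):

    y = 1:  W = log[(1 − π + Q₀π)·Q_A] − log[(1 − π + Q_Aπ)·Q₀]
    y = 0:  W = log(1 − π + Q₀π) − log(1 − π + Q_Aπ)

with the usual simplification for Q₀ = 1.  The upper chart accumulates
C⁺ = max(0, C⁺ + W), signalling when C⁺ > h.  The lower chart
C⁻ = min(0, C⁻ − W), signal C⁻ < −h, is the exact reflection
D = −C⁻ = max(0, D + W) of an upper recursion on the same increments,
so every engine implements only the upper recursion; the exposed lower
path is re-negated.  Run lengths count the signalling patient
(1-based), matching "expected number of patients until a signal".

In all out-of-control computations the chart *weights* stay at their
in-control design values while the *outcome probabilities* use the
shifted π*: this models a chart designed in Phase I confronting a
changed process.

## ARL engines

**Markov chain (discrete mixes).**  The increment distribution has at
most 2(n+1) atoms.  Scaling by γ and rounding onto the integer lattice
turns [0, h] into states {0, …, ⌊γh⌋} plus an absorbing signal state;
the ARL solves (I − Q)L = 1.  Because the jump distribution is
state-independent, I − Q is a Toeplitz matrix plus a rank-one
correction in column 0 (the reflection at zero) and a truncation at
the absorbing top.  The system is therefore solved with a Levinson
Toeplitz solve plus a Sherman–Morrison update — O(m²) time and O(m)
memory for m ≈ γh states — which is algebraically identical to the
generic sparse solve (verified to ~1e−10 relative on small lattices
against dense fundamental-matrix solutions) but makes γ = 2·10⁴
(90,001 states) run in ~30 s.

*Rounding.*  Three schemes:

* `split` (default): each atom's mass is divided between the floor and
  ceiling lattice points with weights equal to the fractional part, so
  the lattice increment has the exact mean of the true increment.
  Empirically the ARL then converges smoothly, approximately like 1/γ
  (reference setting: 7164.42 / 7163.33 / 7162.96 / 7162.78 at
  γ = 2, 5, 10, 20 ·10³).
* `pairwise`: W(s, 0) rounded to the nearest lattice point and
  W(s, 1) placed exactly round(γ·log Q_A) units above it, preserving
  the structural gap between the outcome branches of one score.
* `simple`: independent nearest-integer rounding.

The nearest-integer schemes oscillate by several ARL units in γ
(7159–7187 over the same γ range for the reference setting) because
the rounding errors of 144 atoms drift in and out of phase; `split` is
the default for that reason, and cross-engine agreement with Monte
Carlo is the arbiter of correctness in the test suite.

**Markov chain (continuous mixes).**  States c_i = i·δ on [0, h];
transition probabilities are midpoint CDF differences, the reflected
mass below zero goes to state 0, mass beyond h is absorbed.  Rows are
again state-homogeneous, so the same Toeplitz path applies.  The
scheme is first-order in δ; for smooth increment densities the
`richardson` option removes the leading error term by extrapolating
from statecount/2 and statecount.  For beta mixes with α < 1 the
W-density has an integrable singularity at a branch endpoint and the
convergence is irregular (within ~0.3% of the collocation value at
2,000–4,000 states); piece-wise collocation is the accurate engine for
continuous mixes.

**Piece-wise Chebyshev collocation (continuous mixes).**  The expected
run length from initial statistic u satisfies the Fredholm equation of
the second kind

    L(u) = 1 + L(0)·F_W(−u) + ∫₀ʰ L(z)·f_W(z − u) dz ,

the L(0) term carrying the probability atom that reflection places at
zero.  L is represented on each of M subintervals of [0, h] by its
values at N Chebyshev–Gauss nodes (barycentric Lagrange basis) and the
equation is enforced at those nodes.  Two numerical choices matter:

* *Kink-aligned partition.*  L has derivative kinks where u + W can
  hit 0 or h at a branch-support endpoint.  Those locations (±branch
  endpoints intersected with (0, h), near-duplicates merged, padded to
  M by splitting the widest pieces) are the default subinterval
  boundaries.  At equal system dimension this reduces the error
  substantially versus equal spacing (tested), and it is what makes
  the piece-wise variant stable where a single global polynomial
  (`arl_collocation`, M = 1) creeps toward the solution without
  settling — the package keeps the M = 1 variant for comparison.
* *Kernel integrals in the score variable.*  Instead of quadrature
  against the kinked and (for α < 1) unbounded W-density, each kernel
  integral is transformed back to the score scale x, where the
  integrand is the beta density times a smooth factor.  Segments are
  split where u + w(x, y) crosses {0, piece boundaries, h}, and the
  substitution t = x^α removes the x = 0 endpoint singularity exactly.
  Gauss–Legendre (80 points per smooth segment) then converges
  spectrally.

Defaults N = 40, M = 16 (dimension 640) reproduce the reference
continuous-mix ARLs to well under one part in 7,000; N = 24 and N = 32
at M = 12 agree to ~0.001%.  The condition number of the collocation
matrix is checked (error above ~1e13).

**Monte Carlo.**  Inverse-CDF sampling of the atom distribution inside
a numba-compiled loop; mean and standard error over independent runs.
Used to validate the deterministic engines (3-SE agreement on multiple
parameter sets in the tests), never to produce headline numbers.

## Calibration

ARL(h) is nondecreasing in h — for discrete atoms a fine step function,
which is why the calibrated limit is defined on a grid: `find_limit`
returns the smallest four-decimal h whose ARL reaches the target from
above (the conservative, fewer-false-alarms side of a tie).  A coarse
bisection at a reduced lattice (γ/5, minimum 2,000) brackets the limit
to a few grid steps; the full-γ engine then walks the 10⁻⁴ grid to the
exact first crossing.  This reproduces the published four-decimal
limits for the reference and low-risk mixes to within one grid step
(4.5442 vs 4.5443, 4.0635 vs 4.0636) — one step of slack is the
engine-difference between rounding schemes, well inside the step-width
of the ARL staircase.  For the collocation engine the piece count grows
with h (at least one piece per increment-support width) so the
bracketing phase stays accurate at large h.

## Sensitivity and scenarios

`arl_surface` evaluates ARL₀ on an (α, β) grid at a fixed calibrated
limit (row-major, inclusive endpoints; the canonical full sweep
0.3 ≤ α ≤ 2, 3 ≤ β ≤ 9 at step 0.01 has 102,771 points — the CLI
defaults to step 0.05, with the full sweep opt-in, since the full grid
at γ = 10⁴ is hours of compute).  Per-point engine failures become
NaN rows rather than aborting a sweep.  `oc_profile` sweeps the true
odds ratio Q*; for a one-sided chart the profile is monotone in Q* —
shifts in the matched direction shorten the ARL, opposite shifts
lengthen it beyond ARL₀ (there is no interior maximum; both one-sided
profiles together produce the familiar tent shape around Q₀).

The stream generator draws scores i.i.d. from a pre-change mix and
outcomes as Bernoulli(π*(s)) with odds multiplier Q*_pre, switching
both at a single change-point τ.  It emulates exactly this
data-generating process and nothing more: no serial correlation, no
drift, no covariate-level structure, no risk-model misspecification.
Passing ensemble tests therefore demonstrate the charts' behavior
under the stated model, not robustness to the ways real surgical
series violate it.  Single-realization signal indices are seed
dependent and are never asserted; scenario behavior is validated in
ensemble (detection-delay means against zero-state ARL₁, restarting
the chart at τ so the oracle matches what the engine computes).

## Parameter defaults

| parameter | default | role |
| --- | --- | --- |
| n (max score) | 71 | Parsonnet range 0–71; exposed for other scoring systems |
| (b₀, b₁) | (−3.6798, 0.0768) | Phase-I logistic fit; all headline numbers derive from it |
| Q₀ | 1 | null odds ratio; general Q₀ supported in the discrete path |
| Q_A | 2 and 1/2 | doubling/halving designs of the reference charts |
| γ | 10⁴ (2·10⁴ for final Table values) | lattice scale; ~1/γ bias under `split` |
| rounding | `split` | see above |
| N, M | 40, 16 | collocation degree/pieces, dimension 640 |
| target ARL₀ | 7500 | calibration target of the reference design |
| precision | 10⁻⁴ | four-decimal control-limit grid |

## Known limitations

* The continuous-mix integral-equation path requires Q₀ = 1 and
  b₁ ≠ 0 (monotone inversion of W in the score); the discrete engines
  have no such restriction.
* The continuous Markov engine is first-order and irregular near
  density singularities; it is a cross-check, not the reference.
* Calibration cost is dominated by full-γ ARL evaluations; targets far
  above ~10⁵ patients will need a larger γ for the same relative
  accuracy of the step function.
* Method-of-moments fitting is the only estimator provided (no ML for
  the mix, no goodness-of-fit testing), mirroring the framework's
  scope: the mix is an input to chart design, not an inferential goal.
* The empirical cardiac-surgery records are not distributed with the
  package; model-based results need only the printed parameters, and
  data-dependent quantities (full-score-model ARLs, per-surgeon
  empirical columns) are out of scope.
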