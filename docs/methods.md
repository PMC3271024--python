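# Methods

## Model

The task has three tokens on a horizontal row at x = −D/2, 0, +D/2 (degrees
of visual angle) and a fixation cross 4° off the row, shifted D/4 toward
one side so that it is exactly equidistant (√((D/4)² + 4²)) from the center
token and the nearer side token; at D = 12° this is the 3-4-5 triangle and
the offset is ±3°.  After a single saccade to one token, the target appears
in the left or right token with equal probability.  Post-saccadic target
eccentricities are therefore D/2 for the center strategy and {0, D} for the
side strategy, giving

- P[correct | center] = ψ(D/2)
- P[correct | side]   = w·ψ(0) + (1−w)·ψ(D),  w = P[target on chosen side]

with w = 1/2 for the symmetric target prior.  The retinal sensitivity
function is a four-parameter logistic, decreasing in eccentricity:

ψ(E) = β + (α−β)/(1 + exp((E − E½)/γ)).

This parameterization makes ψ(E½) = (α+β)/2 exactly (the 75%-correct point
when α ≈ 1, β ≈ 0.5), ψ(0) ≈ α for E½ ≫ γ, and asymptote β.  The size
variant mirrors the same family to be increasing in token size, with one
independent member ψ_E(S) per measured eccentricity; members are never
interpolated across eccentricities — querying an unmeasured eccentricity is
an error, and the default 12°-separation geometry needs exactly the
measured set {0, 6, 12}°.

The optimal switch point solves ψ(D/2) = ½ψ(0) + ½ψ(D) in D (or the
analogous equation in S with ψ_{D/2}, ψ_0, ψ_D at fixed D).  Equality holds
trivially at D = 0, so the search interval starts strictly above zero.
Roots are bracketed by a 0.01° sign-change scan and refined by Brent's
method to 1e-4°; the scan doubles as a uniqueness check, and multiple sign
changes raise an ambiguity error rather than silently returning one root.
Expected gain of a policy is Σ_conditions trials × reward × P[correct |
strategy]; MEG takes the per-condition argmax, which coincides with the
step policy through the switch point.

Beyond the 12° mapping grid the side strategy evaluates ψ up to D = 24°;
this relies on the fitted asymptote β and is model extrapolation.

## Fitting

`fit_sensitivity` aggregates trials to per-eccentricity proportions and
minimizes squared error (the default), or maximizes the Bernoulli
likelihood of the raw trials.  Bounds: α, β ∈ [0.5, 1] (chance floor for a
2AFC judgment), E½ ∈ (0, 40], γ ∈ (0, 20]; β ≤ α is enforced by a soft
penalty plus a final clamp.  Optimization is multi-start L-BFGS-B (10
starts: one data-driven, the rest seeded-random within bounds); the best
objective wins, ties broken toward the smaller midpoint.  A fit with
α − β < 0.02 is returned with a `degenerate` flag (chance-level data leave
the location and slope unidentified).  If no start converges, a
`FitConvergenceError` carries per-start diagnostics.  Least-squares and
maximum-likelihood estimates agree within 0.1° on E½ at 1000 trials per
point (tested).

## Synthetic sessions

The generator emulates the experimental protocol, with defaults equal to
the study design:

- mapping grids: eccentricities 0–12° in steps of 3° (experiment 1;
  5×2×2×20 = 400 trials) and sizes 0.6–1.8° in steps of 0.3° at
  eccentricities {0, 6, 12}° (experiment 2; 3×2×2×5×25 = 1500 trials);
- decision schedules: seven values spaced `step` (default 1°) around an
  anchor (by default the observer's switch point, rounded to 0.01°) plus
  the common separations {8°, 24°} — nine conditions, 96 repetitions each
  (864 trials); the size experiment uses five sizes × 112 trials (560);
- saccade endpoints: intended token center + isotropic Gaussian noise,
  σ = 0.75° by default — endpoint scatter comparable to the 1° landing
  criterion, as observed empirically; landings farther than the criterion
  radius from every token abort the trial, which is re-queued with the same
  condition at a uniformly random later position, so retained counts per
  condition always equal the requested repetitions;
- blinks/second saccades: an independent Bernoulli abort (rate 0.15,
  the reported average exclusion rate), also replayed;
- latencies: log-normal, median 250 ms, log-SD 0.25 — plumbing for the
  latency analysis only;
- strategy policies: ideal (the step policy), fixed mixture, sticky Markov
  (repeat the previous strategy with probability κ, else redraw from the
  base rate), always-center/always-side, all with an optional lapse and a
  near-side preference for side saccades (probability the nearer token is
  chosen).

Two modeling choices deserve note.  First, the sticky chain advances only
on completed trials, so the retained-trial sequence analyzed downstream is
itself the Markov chain; this makes κ identifiable from the retained data
via κ̂ = (f_repeat − b)/(1 − b), where b is the base probability of
redrawing the previous strategy.  Second, discrimination outcomes are
Bernoulli with ψ evaluated at the actual landing-to-target distance in the
separation experiment, but at the nominal token-center distance in the size
experiment, because ψ_E(S) is only defined at the measured eccentricities.

What the generator does **not** emulate: saccade kinematics, fixational eye
movements, asymmetric or condition-dependent strategy biases, learning or
fatigue across sessions, and any perceptual change induced by the preceding
saccade.  Passing tests therefore demonstrate correctness of the analysis
machinery under the stated statistical model, not fidelity to any
individual human data set.

## Analyses

Saccades are assigned to the nearest token in Euclidean distance; exact
ties break to the center token, then left (deterministic and of measure
zero under continuous noise).  Exclusions (aborts, blinks, stray landings)
are tallied by reason.  Strategy proportions carry Clopper–Pearson
intervals.  Inter-trial dependency compares the conditional
strategy-repeat frequency with the unconditional frequency, per observer,
and tests the difference across observers with a one-tailed paired t-test
(with fewer than two observers the test is skipped with a notice).
Repeated-condition optimality compares the optimal-choice rate on
immediately repeated conditions against the remaining trials with a
one-tailed two-proportion z-test.

The gain analysis reports realized gain (reward × correct count), the model
expected gain of the observed strategy mix, MEG over the same per-condition
counts, and the relative deficit (MEG − EG)/MEG.  The nested test of gain
maximization models per-condition success counts as binomial: under the
null with the MEG strategy's model probability, under the alternative with
one free probability per condition; 2·(logL_alt − logL_null) is referred to
χ² with one degree of freedom per condition.  Granularity is per-condition
rather than a single pooled binomial so that the null is properly nested
and the test is sensitive to condition-wise misallocation.  Zero-trial
conditions are dropped with the degrees of freedom adjusted.

ψ can be re-estimated from decision or verification sessions: each retained
trial contributes (distance from the landed token center to the target,
correct), which spans eccentricities {0, D/2, D} across the schedule; the
default optimality judgments use the mapping-phase fit, with the refit
available as a robustness check.

## Numerical choices and problem sizes

Root tolerance 1e-4°, uniqueness scan at 0.01°, brute-force test oracles at
0.001°.  Monte-Carlo checks in the test suite use the experimental design
scale (400-trial mapping sessions, 864-trial decision sessions) with
replicate counts of 100–500 chosen to keep binomial error well inside the
asserted tolerances.  The type-I calibration of the likelihood-ratio test
simulates the gain-maximizing observer with zero endpoint noise: endpoint
scatter perturbs the realized success probabilities away from the nominal
model values, which is a model-mismatch effect distinct from the
calibration of the statistic itself.

## Limitations

- The χ² reference for the nested test is asymptotic; with success
  probabilities near 1 and small per-condition counts it can run
  conservative.
- The schedule builder treats the two common separations identically to the
  seven observer-specific ones.
- Size-experiment outcomes use nominal token eccentricities (see above), so
  endpoint noise affects classification but not discrimination difficulty
  in that variant.
- The sticky-Markov policy is symmetric in κ across strategies; empirical
  repeat tendencies may differ by strategy.
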