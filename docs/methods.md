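# Methods

This note documents the models, conventions and numerical choices behind
discountlab, and what the synthetic-agent simulations do and do not show.

## The staircase and its conventions

Each (delay, run) cell elicits one indifference point by interval bisection
over the grid of immediate options.  Levels are indexed by **ascending
immediate value** (level 1 = 13 % of the photograph visible or $1; level
L = the full photograph or $100).  Choosing the delayed option at a
presented level means the immediate offer was not attractive enough, so the
lower bound of the uncertainty interval rises to that level; choosing the
immediate option lowers the upper bound to it.  (Task descriptions that
index by *occlusion* order levels the other way; the two are mirror images
under level ↔ L + 1 − level, and a unit test pins the published example
trace under that relabeling.)

The interval is tracked as the half-open (lo, hi] over 0..L+1 so that the
extreme levels are genuinely tested: hi = L + 1 encodes an agent that never
accepted any immediate offer.  The presented level is ⌊(lo + hi)/2⌋, which
reproduces the canonical trace (first presentation at the middle level, then
the quarter point).  A cell is converged when hi − lo = 1; the indifference
point is the lowest level the agent accepted.  Sessions that never accept
(hi = L + 1) are recorded at the maximum level with an `always_delayed`
flag and retained downstream; sessions accepting even the minimum offer are
flagged `always_immediate`.

With 10 levels plus the never-accepts outcome there are 11 distinguishable
results per cell, so any deterministic bisection needs 3 or 4 choices per
cell (⌈log₂ 11⌉ = 4): per-session totals over 22 cells necessarily range
from 66 (all-3 agents, e.g. a threshold at the bottom level) to 88 (all-4
agents, e.g. exclusive delayed preference), with a mean of 3.55 trials per
cell over the exhaustive enumeration of threshold agents and start levels.
Agents whose switch point falls inside the delay grid mix 3- and 4-trial
cells and land in the 70–80 band typical of real sessions.  The first trial
of each cell is drawn from the middle start pool ({4, 5, 6} of 10 levels;
{7, 8, 9} of 14 for the hypothetical grid); the two runs are interleaved
with uniformly random cell selection.  Response-buffer and display
durations are bookkeeping only; nothing sleeps.

## Agents and choice noise

An agent carries a discounting curve on the normalized subjective-value
scale SV′ (hyperbolic rate k, or logistic slope a and log-delay switch
point b) and compares the normalized immediate value against SV′(delay).
With temperature tau = 0 the larger value wins and ties go to the delayed
option; with tau > 0 the choice is a softmax draw at temperature tau on the
normalized value scale.  The default tau = 0.002 keeps staircases monotone:
the finest normalized grid step of the experiential task is ≈ 0.023, and
temperatures approaching that step (e.g. 0.02) turn top-of-grid choices
into near coin flips, visibly attenuating every downstream slope estimate.
Real participants' choice stochasticity is unknown; tau is a free artifact
parameter.

## The synthetic population

Defaults are pinned to the published sample anchors: state anxiety
34.3 ± 10.1, trait 43.0 ± 10.8, correlation 0.59 (bivariate normal);
experiential logistic group effects (intercept −13.5 ± 1.0, slope
4.3 ± 0.5 between agents, giving a = slope and b = −intercept/slope);
hypothetical group effects (−12.4, 1.8); rating slope −0.55 per occlusion
level with intercept 3.3, between-participant slope SD 0.10 and trial noise
SD 1.4, chosen so that per-participant |occlusion–pleasantness r| averages
≈ 0.73 with spread ≈ 0.16 after Likert discretization (round half away from
zero, clip to [−4, 4]).

Anxiety effects are carried by the *generating parameters*, not by AUC
directly: the rating-slope magnitude (the mediator carrier) is linear in
standardized state and trait anxiety, and the experiential switch point b
is linear in the realized slope magnitude, trait anxiety and the
state × trait product, with Gaussian disturbances; the hypothetical b
carries the (weak, negative) trait effect.  Coefficients were set once so
that the implied standardized regressions at large n sit near the published
path anchors (state → sensitivity ≈ −0.48, sensitivity → experiential AUC
≈ 0.55, trait → experiential AUC ≈ 0.40, trait → hypothetical AUC ≈ −0.28,
cross-task AUC correlation ≈ −0.1).  At n = 44 a single draw wanders
considerably around these values; the tests therefore assert recovered
*sign patterns* at study size and quantitative recovery only at large n.

What the generator does not emulate: reaction times, photograph content,
session order, drifting attention, or any within-session nonstationarity.
Passing tests show the analysis chain is correct and calibrated for agents
of the assumed form, not that real participants behave like those agents.

## Curve fitting and AUC

Per-participant fits minimize squared error of SV′ over bounded parameters
with a multi-start grid (a ∈ {0.25, 1, 4, 16} × five b values spanning the
log-delay range ± 2; k log-spaced over [1e−6, 10]), best start winning,
ties broken by lower RMSE then lower a.  Both staircase runs enter as
separate observations.  R² is reported against the mean of the
observations and may be negative; RMSE is the root mean squared residual.
A three-parameter variant with a floor asymptote, SV′ = c + (1 − c)·logistic,
is available but flagged experimental.  The model-based AUC integrates the
fitted two-parameter logistic curve over the delay interval on the linear
time axis, normalized by (t_max − t_min); the quadrature runs on the
log-time substitution for stability at large slopes and matches a dense
trapezoid oracle to < 1e−6.  An AUC on the linear axis weights long delays
heavily; the log-axis alternative was considered and rejected to keep the
standard AUC convention.

## Mixed models and boundary handling

Y = log((1 − SV′)/SV′) linearizes both families.  All mixed models use
maximum likelihood (never REML) so AIC/BIC and likelihood-ratio comparisons
across fixed-effect structures are valid; the logistic model estimates an
unstructured 2 × 2 random intercept/slope covariance; the hyperbolic model
enters log-delay as a fixed offset (coefficient 1) with random intercepts.
The null-versus-hyperbolic comparison has a zero counted-parameter
difference and is reported with df = 0 and a note.  Parameter counts:
3 (null, hyperbolic), 6 (logistic).  Marginal and conditional R² follow the
variance-partitioning definition, with the random-effect variance averaged
over the observed design for random-slope models.

Indifference points at the extreme grid levels give SV′ ∈ {0, 1}, where the
transform diverges.  Two conventions are implemented.  The default
(`boundary="drop"`) excludes those observations: the 10-level grid can only
express transformed values between ≈ −3.33 (the second-highest level) and
≈ +1.57 (the second-lowest reachable level), so winsorized boundary values
act as a censoring floor that flattens any fitted slope — fits to clamped
data recover group slopes of ≈ 1–2 when the generating slope is 4.3,
whereas dropping boundary rows recovers the generating fixed effects
within sampling error.  The alternative (`boundary="clamp"`) winsorizes
SV′ by eps = half the smallest normalized level step of the task grid
(experiential ≈ 0.0115), computed from the configuration rather than
hard-coded.  Dropping loses the exclusively-delayed sessions from the
mixed models (they remain in curve fits and AUC, at the boundary value
with a flag); clamping keeps them at the price of the censoring bias.

## Scalar statistics

Welch tests are computed from summary triples (mean, SD, n) with
Welch–Satterthwaite df floored to an integer for reporting; Cohen's d uses
the plain mean of the two SDs as standardizer (nonstandard, but it
reproduces printed values computed that way).  The correlation Bayes factor
places a stretched symmetric beta prior on the population correlation
(shape 1/scale; default scale 1/3, the reference "medium" default) and
integrates the exact sampling density of r numerically; the posterior
median comes from quantile inversion on a grid rather than MCMC.  The
implementation agrees with an independent reference implementation to four
decimals and reproduces BF₁₀ = 0.339 at r = −0.014, n = 44.  The paired
signed-rank test is exact for n ≤ 25 without ties; V is the sum of ranks of
positive differences.

## Path analysis

Recursive observed-variable models are estimated by minimizing the
normal-theory ML discrepancy between the implied and sample covariance
(free parameters: exogenous variances/covariance, regression paths,
residual variances, and the experiential–hypothetical residual covariance),
started from equation-wise OLS — which is already the ML solution for the
saturated no-mediation model, verified to 1e−6 in tests.  Standard errors
come from the observed information; standardized coefficients are reported
both fully standardized (x and y scaled) and predictor-standardized, since
either convention can sit behind published values.  CFI uses the
independence baseline, RMSEA the noncentrality (χ² − df)/(df (n − 1)), and
SRMR the standardized residual moments; saturated models return CFI = 1
and RMSEA = 0 exactly.  Indirect effects are path products with
delta-method SEs.  The moderation regression uses raw (uncentered) anxiety
scores, matching the scale on which such interaction coefficients
(≈ 5e−4 per product unit) are conventionally printed.  The split-half
illustration median-splits trait anxiety and correlates state anxiety with
experiential AUC within each half.

## Problem sizes and determinism

The shipped analyses run 44 agents per study; recovery simulations use 44
agents (matching the study design) and large-n checks use 2 000–5 000
draws.  Every stochastic stage takes an explicit seed; a single top-level
seed fans out to named substreams, and identical seeds reproduce byte
-identical CSV output.  The full synthetic pipeline at n = 44 completes in
well under a minute on one CPU.

## Known limitations

- The 10-level grid quantizes indifference points coarsely near the top of
  the scale (steps of 0.02–0.08 in visible fraction); slope estimates from
  clamped boundary values are biased low, which is why boundary dropping is
  the default (see above).
- At the default experiential anchors the group switch point (≈ 23 s) lies
  near the top of the 1–25 s delay grid, so many synthetic sessions are
  ceiling-dominated, exactly as a large minority of real sessions were;
  group-level recovery relies on the informative tail delays.
- Reward sensitivity is measured as |r| from 60 discretized ratings; the
  measurement noise attenuates mediation estimates at study size relative
  to the generating structure.
- ML path analysis assumes multivariate normality and complete cases; there
  is no latent-variable modeling, bootstrap CI, or missing-data handling.
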