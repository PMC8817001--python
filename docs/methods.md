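# Methods

`tacitcoord` analyzes individual ability in tacit coordination games of the
"Assign Circles" family: a board shows two squares and a set of circles on an
integer grid, and two players who cannot communicate each attach every circle
to one square, scoring a point only when their full assignments coincide.
This note records the models, conventions, and numerical choices behind each
stage, and what the synthetic cohorts do and do not establish.

## Boards and assignments

Coordinates are integer grid points with the origin at the top-left corner,
x rightward and y downward; squares and circles occupy cell centers.  Circles
are kept in canonical order — ascending x, ties broken by ascending y — so an
assignment is a string over {L, R} whose i-th letter attaches the i-th
canonical circle.  The solution space of an n-circle board has 2^n full
assignments.  Boards are stored as JSON, cohorts as CSV (one row per player,
one column per board), both human-inspectable.

## Selection rules

Three focal-point heuristics are modeled.  Each applies on a board only when
it pins down a unique full assignment:

* **closeness** — each circle goes to its strictly nearer square;
* **accession** — circles are grouped into coherent groups (4-connected on
  the grid: horizontal or vertical neighbors only, not diagonal), and each
  whole group goes to the square nearer to the group, the group-to-square
  distance being the minimum over its circles;
* **equality** — if a vertical line splits the circles into two strictly
  separated halves of equal size, the left half goes to the left square.
  An odd circle count, or a circle on every candidate split line, blocks it.

Distances are Euclidean, but all comparisons use exact integer squared
distances, so equidistance ("ties") is detected deterministically and any tie
renders the rule inapplicable.  Because canonical order is x-major, the
equality assignment is always L^(n/2) R^(n/2).  The package ships ten fixed
fixture boards whose rule pattern reproduces the documented applicability
table of the classic ten-game set (same circle counts, same implied
assignments, same "none" cells); their coordinates are synthetic
reconstructions, since the historical layouts exist only as figures.

## Coordination statistics

For one game with N players, where m_j players chose solution j, the
coordination index is

    CI = sum_j m_j (m_j - 1) / (N (N - 1)),

the probability that two players drawn without replacement coincide; under
uniform random picking its expectation is 1/2^n.  A player's individual
coordination ability (iCA) is their mean pairwise agreement with every other
player over the t predefined games (the random filler boards differ between
sessions, so they are excluded; both choices are parameters).  Agreement is
full-assignment agreement: one differing circle breaks coordination.

Per player, game, and rule, the game tag GT is +1 (rule applied, player
matched its implied assignment exactly), -1 (applied, not matched), or 0
(rule inapplicable).  The strategy rate SR of a rule is
(# GT = +1) / (# GT != 0) over all games, predefined and random; a player for
whom a rule was never available gets a missing SR and is excluded from the
profile model with a warning.  "Followed the rule" deliberately means exact
full-assignment match — rules imply unique full assignments, and partial
credit would not compose with the agreement-based statistics.

Group comparison of the three SR dimensions uses a one-way ANOVA plus Tukey
HSD (studentized-range, via scipy); a within-player permutation F test is
provided as a small-sample fallback.  The utilization-versus-difficulty
relationship (per-game share of rule-followers against per-game CI) is an
ordinary least-squares line with a two-sided slope test.

## Ability distribution

**Dip statistic.**  Hartigan's dip — the sup-distance from the empirical CDF
to the nearest unimodal CDF — is implemented from the published algorithm:
the greatest convex minorant touches the lower corners of the ECDF steps, the
least concave majorant the upper corners, and the candidate modal interval is
iteratively narrowed to the stretch of largest GCM–LCM gap while the
one-sided deviations outside it bound the dip.  The implementation is checked
in the test suite against an independent brute-force oracle that bisects on d
and decides, by linear programming, whether some unimodal CDF fits inside a
d-band around the ECDF (convexity/concavity and monotonicity as linear
constraints over candidate modes, including tied samples).  P-values are
bootstrap quantiles of the dip under the uniform null at the same n (the dip
is invariant under strictly increasing transforms, so the uniform null is
generic); a precomputed null table can be shared across tests.  Default 2000
bootstrap draws.

**Mixture fit.**  The score histogram (default 20 bins over [0, 1]; the
score range is known, and a fixed binning keeps fits comparable across
cohorts) is fit by least squares with the amplitude-Gaussian curve

    f(x) = sum_i a_i exp(-((x - b_i)/c_i)^2).

This is deliberately a curve-fit parameterization with free amplitudes, not
a weight-normalized probability mixture: published fits of this form carry
amplitudes far above any normalized density, so refitting user data in the
same form keeps parameters comparable.  (An EM-fitted normalized mixture
would be the statistically standard alternative; the curve-fit form is the
one this pipeline reproduces.)  Optimization is multi-start trust-region
least squares with an analytic Jacobian: centers start on sample quantiles
plus seeded jitter, widths at the sample scale over k, 20 restarts by
default.  Note c_i = sigma_i * sqrt(2) for a Gaussian of standard deviation
sigma_i.

**Choosing k.**  Fits are nested by seeding each k with the previous best
solution plus one negligible component, so RSS is non-increasing in k.  The
elbow picks the first k whose RSS improvement at k+1, measured relative to
the histogram's total variation about its mean (i.e. the gain in R^2), falls
below 10% (configurable).  Normalizing by the *current* RSS instead would
never stop on clean data, because near-zero residuals still shrink by large
relative factors.  Separately, one-dimensional k-means clusterings are scored
by the silhouette index over k >= 2 (silhouette is undefined at k = 1) and
the argmax is reported as corroboration; the elbow k is the operative choice.

## Profile model

The (SR_closeness, SR_equality, SR_accession) triples are z-scored per
dimension; the covariance of the standardized data is eigendecomposed and
components are sorted by eigenvalue magnitude.  Each eigenvector's
largest-magnitude loading is made positive, fixing the sign convention
across linear-algebra backends.  S1 and S2 are projections of the
standardized profile on the top two components; retained variance for m
components is 1 - sum||x - x_approx||^2 / sum||x||^2 on the standardized
vectors (100% at m = 3 by construction).  Projections use the standardized
path throughout; coefficients refit on raw-loading projections would differ
in scale.  Ability is regressed on (1, S1, S2) by OLS (statsmodels), and
reported with R^2, the overall F statistic, and the residual variance.
Validation reports per-player relative absolute error
|observed - predicted| / observed * 100 and its 25/50/75th percentiles
(linear interpolation); players with a zero observed score are excluded with
a warning.

## Synthetic populations

No generative model of players is published, so the agent model is this
package's construct: a two-level mixture chosen because its strategy-rate
expectations are analytically computable.  With probability `noise` the agent
picks uniformly from the 2^n assignments; otherwise it samples among the
assignments implied by the applicable rules with probability proportional to
the summed propensities of the rules implying each one (coinciding rules pool
their mass); with no applicable rule it picks uniformly.  One master seed is
split into per-agent streams, so any agent's choices regenerate
independently.

The default cohort mirrors the emulated design: 93 agents, the 10 fixture
boards plus 4 random boards, and three ability strata — 30% low-noise
(noise ~ U[0.02, 0.08]), 40% mid-noise (U[0.18, 0.28]), 30% high-noise
(U[0.45, 0.95]) — with per-agent rule propensities drawn from a
Dirichlet(4, 4, 2), favoring closeness and equality over accession.  These
defaults emulate the reported distribution shape qualitatively (two tighter
high-ability groups, one broad low-ability group); exact published mixture
parameters are not targeted.  Under the defaults the strata overlap enough
that the dip test usually does *not* flag the 93-player ability distribution
— consistent with the modest dip reported for the real cohort — so the
dip-power property test uses a sharply separated three-strata configuration
(noise bands [0, 0.02], [0.35, 0.40], [0.85, 1.0]), where the test flags
multimodality in >= 80% of replicates at n = 300.

What the synthetic cohorts do not emulate: human salience beyond the three
rules (real players coordinate above chance even where no rule applies;
pure-noise agents cannot), session effects, learning, or any correlation
structure between propensities and noise beyond stratum membership.  Passing
tests therefore establish that the statistics, distribution characterization,
and model recover known structure from data of the study's shape — not that
the generator reproduces human behavior.

## Problem sizes and determinism

Tests and the acceptance script size their simulations to run in minutes on
one CPU: cohorts of 15–300 agents, 200-replicate Monte-Carlo checks,
bootstrap tables of 500–2000 draws shared across checks where the statistic
permits it.  Every stochastic stage takes an explicit seed; a pipeline run
with the same config and seed is byte-identical.

## Known limitations

* The dip p-value is a bootstrap from the uniform null; for very small n the
  discreteness of the bootstrap limits resolution.
* The histogram-based mixture fit inherits binning bias; bin count is a
  reproducibility parameter, not an adaptive choice.
* With 20 bins, fitted mixtures with k >= 7 can reach zero residual
  (saturation); k selection is only meaningful well below that.
* Equality's applicability is decided on x-coordinates alone, per its
  median-line definition; boards designed adversarially around equal-x
  columns simply render it inapplicable.
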