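# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of the `prefnr` pipeline.

## Preference model

A listener's preference over noise-reduction strengths g (maximum gain
reduction, dB) is modelled with a quadratic utility

    u(g) = a·g + b·g²

and the probability of choosing the first of two presented strengths is the
logistic of the utility difference, P = σ(u(g₁) − u(g₂)). The model embodies
a trade-off: stronger NR removes more residual noise but adds speech
distortion, so utility can rise and then fall in g. Assumptions worth making
explicit:

- **No intercept.** Any constant in u cancels in the difference; the model
  is deliberately fit without one (the log-likelihood is invariant to
  u → u + c). An optional presentation-order bias term δ in the linear
  predictor is available (`order effect`), default off, because the design
  balances AB/BA orders rather than modelling them.
- **No lapse rate and no ties.** Trials are two-alternative forced choices;
  attention lapses are absorbed into the Bernoulli noise.
- **Independence.** Trials are treated as independent Bernoulli draws given
  (a, b); test–retest correlation within a pair is not modelled.

**Preferred strength.** With b < 0 the utility peaks at −a/(2b); this value,
clamped to the tested interval [0, 18] dB, is the response feature
G_min_opt. For convex or linear utility (b ≥ 0) the optimum is the endpoint
with higher utility; the exactly-tied case returns the interval midpoint
with a degenerate-fit flag (no preference information, deterministic
output).

**Fitting.** The 2-parameter negative log-likelihood is minimised by BFGS
with analytic gradient, gradient tolerance 1e−8, at most 500 iterations.
The covariance of (a, b) is the inverse observed information (logistic
Hessian) at the optimum. *Separation* — a responder whose choices are
perfectly predicted, e.g. "always prefer stronger" — makes the MLE diverge
along a ray; it is detected when the coefficient norm exceeds 50 (at which
point the smallest utility gap on the study grid already saturates the
choice probabilities) or the total NLL falls below 1e−4 per trial. Separated
fits report the favoured endpoint as G_min_opt with the covariance set to
NaN and flagged unreliable.

**Preference curves.** The model-implied win fraction at level g is the mean
of P(g over g′) across the other design levels — the same averaging that
produces empirical win fractions, so curve and data are directly
comparable. Pointwise standard errors propagate the coefficient covariance
by the delta method. Note that a flat utility does *not* give identical SEs
across levels on an asymmetric grid (the information differs per level);
SEs are only pairwise equal under grid mirror symmetry.

## Experimental design and win counts

The full design crosses 10 strengths (0, 4, 6, 7, 8, 9, 10, 12, 16, 18 dB)
in all 90 ordered pairs, twice: 180 trials per participant, each level
appearing 36 times. The enumerator is deterministic (lexicographic by first
level, second level, repetition); presentation-order randomisation is the
caller's concern, with their own seeded RNG. Win fractions use per-level
appearances as denominator, so profiles remain comparable on subsampled
data; levels with zero appearances in a subset carry an *undefined* (NaN)
fraction, never 0 — imputing 0 would fabricate strong dispreference.

## Group statistics

G_min_opt is analysed as a response feature: Bartlett's test for
homoscedasticity, a Kolmogorov–Smirnov normality screen on group-centred
values (plain KS with estimated parameters by default — the conventional if
slightly anti-conservative usage; a Lilliefors-corrected option is
provided), Kruskal–Wallis with mid-rank tie correction across the three
groups, and Dunn's z-tests on pooled mean ranks with Bonferroni m = 3 as the
post hoc. Spearman correlations relate G_min_opt to PTA, SRT and age;
pairs with a missing member (absent SRT) are dropped; the p-value is exact
(permutation) for n ≤ 9 and t-approximate otherwise. Degenerate inputs are
deterministic: an all-tied Kruskal–Wallis sample returns H = 0, p = 1.

The design-stage power calculation uses the two-sample normal approximation
n = 2σ²(z₁₋α/₂ + z_power)²/Δ² rounded to the nearest integer; with
σ = 1.8 dB, Δ = 2.5 dB, α = 0.05 and power 0.80 this gives n = 8 per group.
A stricter noncentral-t variant (`method="exact-t"`, ceiling) is provided
and clearly labelled; it returns a slightly larger n.

## Clustering

Participants are clustered on their win-fraction vectors with the Manhattan
(L1) distance — robust to outlier listeners — and Ward's minimum-variance
criterion applied through the Lance–Williams recurrence

    d(ij,k) = [(nᵢ+nₖ)d(i,k) + (nⱼ+nₖ)d(j,k) − nₖ d(i,j)] / (nᵢ+nⱼ+nₖ)

to the dissimilarities **as given** (the `ward.D` convention of R's hclust),
which is not the squared-distance `ward.D2` semantics common elsewhere; the
squared variant is available behind a flag. The agglomerator was verified
against R `hclust(method="ward.D")` (identical heights and topology) and is
continuously tested against a naïve O(n³) reference implementation. Ties in
the minimal dissimilarity merge the lexicographically smallest cluster ids —
deterministic given canonical participant order. Distances are computed on
win *fractions*; on the full design this differs from raw counts only by
the constant factor 36 and so leaves the clustering invariant, while
fractions generalise to reduced designs.

Stability of a k-cluster solution is formalised as its dendrogram
*lifetime*: the height of the merge reducing k to k−1 clusters minus the
height of the merge reducing k+1 to k, with the root merge bounding k = 2.
Lifetimes telescope to (root − first merge) and rank candidate cluster
counts. Cluster centroids are arithmetic means of member win fractions with
across-participant sample SD; singleton clusters report SD 0, flagged.

## Comparison-budget simulation

The reduced design keeps levels 0, 7, 8, 9, 10, 18 dB and the ordered pairs
(0 vs each mid) + (18 vs each mid) + (0 vs 18), the last doubled to raise
the weight of the only direct low-vs-high comparison: 8 + 8 + 2×2 = 20
pairs, 40 trials with two repetitions. The doubled pairs are distinct pool
entries and can both be drawn. Per replicate, n trials are drawn uniformly
without replacement, the drawn win fractions computed per level, and the
draw assigned to the nearest cluster centroid (restricted to the reduced
levels) by Euclidean distance. Two conventions the original description
leaves open are resolved as follows and are configurable in principle:
levels with zero appearances in a draw are *excluded* from the distance
(not imputed), and exact distance ties split the assignment count equally.
The default replicate count is 500; one `numpy.random.default_rng` stream
seeded once governs a whole budget curve, so results are bit-reproducible.
An adaptive-sampling strategy (use earlier answers to pick the next pair)
would improve on this average-case estimate; it is deliberately out of
scope.

## Synthetic cohorts

`generate_cohort` emulates the study conditions: groups NH / HI-mild /
HI-moderate of 10 listeners with preferred-strength medians 8.2, 11.6 and
15.7 dB. Choices of generator laws, where the study conditions do not pin
them down:

- **G_min_opt distribution:** normal with SD 3.8 dB (between the 3.6 and
  4.0 dB spreads reported for comparable listener groups in earlier work),
  truncated to [0, 18] dB. The location parameter is calibrated so that the
  *truncated* distribution's median equals the group target — naive
  truncation would otherwise drag the HI-moderate median visibly below
  15.7 dB.
- **Curvature:** b ~ uniform[−0.06, −0.01], spanning flat to sharply peaked
  preference curves; a = −2·b·g* places the utility vertex exactly at the
  drawn optimum (recorded in the truth table to machine precision).
- **Covariates:** better-ear PTA uniform within the group range (NH 0–20,
  HI-mild 20–40, HI-moderate 40–70 dB HL); age = 30 + 0.55·PTA + N(0, 14)
  years clipped to [18, 95]; SRT = 18 + 0.85·PTA + N(0, 7) dB. These land
  pooled Spearman correlations of PTA with age near 0.6, matching the
  moderate associations such cohorts show. The first five NH participants
  carry no SRT, mirroring the missing measurements in the study design.
- **Seeding:** one master seed spawns a per-participant `SeedSequence`
  substream keyed by (group index, member index), so a participant's draws
  are unchanged when other groups are resized.

`archetypes` builds the stylised three-cluster cohort (6 / 9 / 15 members
preferring no NR, ~10 dB, and maximal NR). Archetype responders are
*deterministic* utility maximisers — boundary preferrers via a steep linear
utility with near-zero curvature, the intermediate archetype via a strong
vertex at 10 dB; equal-utility ties fall back to the first presentation,
which the balanced design turns into a 0.5 win fraction. The `noise_sd`
parameter adds independent Gaussian noise (win-fraction units) to each
level of each profile, clipped to [0, 1]; at `noise_sd = 0` recovery of the
planted partition is exact by construction. Trial-level records stay
deterministic, which is what the budget simulation consumes.

**What the generator does not emulate:** real listeners' sequential
dependencies (fatigue, learning, criterion drift), lapses and attention
failures, audiogram shape beyond the PTA summary, heterogeneous test–retest
reliability, and any acoustic property of the stimuli. Passing tests on
synthetic cohorts therefore demonstrate that the *pipeline* is correct and
well-calibrated under its own assumptions, not that those assumptions hold
for any particular listener population.

## Problem sizes and numerical conventions

Default problem sizes, chosen to make every check statistically meaningful
at desk scale: parameter recovery uses 200 simulated listeners × 180 trials
(median |error| ≈ 0.35 dB, |bias| < 0.1 dB); planted-partition recovery uses
50 seeded archetype cohorts at per-level noise SD 0.1; budget curves use 500
replicates per budget; the exhaustive budget oracle enumerates all 40
leave-one-out subsets at budget 39. Level equality is exact (the study grid
is integer-valued; no float tolerance on grid membership). Merge-height and
distance ties use a 1e−12 absolute guard. The acceptance script derives all
sub-seeds from a single `--seed` via `SeedSequence`.

## Known limitations

- The QUL likelihood here is the minimal quadratic-utility/logistic-link
  form with no nuisance parameters; richer variants (lapse rates, order
  effects on by default, hierarchical pooling across listeners) are not
  implemented.
- Pointwise curve SEs are delta-method approximations; they understate
  uncertainty for near-separated fits (which are flagged instead).
- The lifetime ranking formalises "persists over a large height range" but
  any such scalarisation of dendrogram stability is a convention.
- The budget simulation is average-case by design; adaptive comparison
  selection would need fewer trials and is not modelled.
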