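# prefnr

Paired-comparison analysis of preferred noise-reduction (NR) strength in
hearing aids.

Single-channel NR algorithms attenuate estimated background noise in
speech-in-noise signals; their strength is governed by the maximum gain
reduction G_min (the "spectral floor", in dB). Listeners differ in how much
NR they like — stronger NR removes more noise but distorts speech — and this
package implements the complete statistical pipeline for measuring and
analysing that preference from two-alternative forced-choice listening
tests: which G_min does a listener prefer, does hearing loss shift the
preference, how few distinct NR settings cover a population, and how few
paired comparisons are needed to pick the right setting for an individual.

It is written for hearing researchers and audiology methodologists; the raw
input is a table of paired-comparison trials (first/second stimulus strength
in dB, forced choice, repetition) plus participant covariates (hearing-loss
group, better-ear pure-tone average PTA at 1, 2, 4 kHz in dB HL, age,
optionally the speech reception threshold SRT).

## The model

Preferences are modelled with a quadratic-utility-logistic (QUL)
paired-comparison model. Strength *g* carries utility

u(g) = a·g + b·g²,  P(choose first | g₁, g₂) = σ(u(g₁) − u(g₂)),

with σ the logistic function; the intercept cancels in the difference, so
(a, b) are the only parameters. With concave utility (b < 0) the preferred
strength is the vertex G_min_opt = −a/(2b), clamped to the tested range
(0–18 dB) to avoid extrapolation. Fits are maximum likelihood with
covariance from the observed information; perfectly monotone responders
(separation) are detected and reported as endpoint optima.

Downstream, each participant reduces to the response feature G_min_opt,
compared across hearing-loss groups with Kruskal–Wallis / Dunn–Bonferroni
and correlated with PTA, SRT and age by Spearman rank correlation. A
data-driven view clusters the per-level win-count profiles (Manhattan
distance, Ward linkage applied to unsquared dissimilarities, the
`hclust ward.D` convention) and ranks cluster counts by dendrogram lifetime.
A resampling simulation then estimates, for a reduced six-level design
(0, 7, 8, 9, 10, 18 dB; 20 weighted ordered pairs, 40 trials), the
probability that n randomly drawn comparisons place a listener in the
correct preference cluster.

Because no raw listening data ship with the package, a seeded synthetic
cohort generator emulates the study design end to end: three groups of ten
listeners with group preferred-strength medians 8.2 / 11.6 / 15.7 dB,
trial-level Bernoulli choices drawn from the same QUL model, and PTA / age /
SRT covariates with realistic associations.

## Worked example

```python
import numpy as np
from prefnr import qul_model as qm, synthetic_cohort as sc, trial_design as td

rng = np.random.default_rng(42)
# a listener whose true preferred strength is 8 dB (a = -2*b*g*)
trials = sc.simulate_trials("p1", a=0.48, b=-0.03, design=td.STUDY_DESIGN, rng=rng)
fit = qm.fit_qul(trials, clamp=(0.0, 18.0))
print(f"g_opt = {fit.g_opt:.2f} dB  (a = {fit.a:.3f}, b = {fit.b:.4f}, "
      f"separated = {fit.separated})")
```

prints

```
g_opt = 8.35 dB  (a = 0.576, b = -0.0345, separated = False)
```

i.e. from 180 simulated forced choices the model recovers the generating
optimum of 8 dB to within 0.4 dB; `fit.covariance` gives the coefficient
uncertainty and `qm.preference_curve(fit, td.STUDY_DESIGN)` the expected
win fraction per level with pointwise delta-method standard errors.

The full analysis is scripted as numbered drivers:

```
python analysis/01_simulate_cohort.py     # synthetic cohort -> results/data/
python analysis/02_fit_preferences.py     # per-participant QUL fits
python analysis/03_group_statistics.py    # group tests + correlations
python analysis/04_cluster_preferences.py # win-profile clustering
python analysis/05_comparison_budget.py   # budget resampling
```

On the default seed the drivers report, among other things, a significant
Kruskal–Wallis effect of hearing-loss group on preferred strength with the
NH vs HI-moderate pair significant post hoc, a positive Spearman correlation
of preferred strength with PTA, and a median probability of correct cluster
assignment crossing 80% at a budget of 15 comparisons.

The same functionality is exposed as a CLI (`prefnr design|simulate|fit|
stats|power|cluster|budget`); run `prefnr --help`.

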