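"""Comparison-budget resampling: how few paired comparisons suffice?

A full round-robin preference measurement (180 trials) is too long for the
clinic.  This module reproduces the budget simulation: restrict to six
strength levels (0, 7, 8, 9, 10, 18 dB — roughly the preferred strengths of
the three preference clusters), keep only the pairs that pit an extreme
against a mid level or the two extremes against each other (the 0-vs-18
pairs doubled, 8 + 8 + 2x2 = 20 ordered pairs; 40 trials with two
repetitions), then repeatedly draw n of those 40 responses uniformly without
replacement and classify the drawn win profile to the nearest cluster
centroid by Euclidean distance.  Repeating the draw estimates the
probability of landing in the participant's true cluster as a function of
the budget n.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .trial_design import Design, Trial, win_profile

__all__ = [
    "ReducedDesign",
    "BudgetCurve",
    "STUDY_REDUCED_LEVELS",
    "build_reduced_design",
    "reduced_trial_pool",
    "subsample_classify",
    "budget_curve",
    "restrict_centroids",
]

#: The six levels of the study's budget simulation.
STUDY_REDUCED_LEVELS: tuple[float, ...] = (0, 7, 8, 9, 10, 18)
STUDY_MID_LEVELS: tuple[float, ...] = (7, 8, 9, 10)
STUDY_EXTREMES: tuple[float, float] = (0, 18)


@dataclass(frozen=True)
class ReducedDesign:
    """A weighted multiset of ordered pairs over a reduced level grid."""

    levels: tuple[float, ...]
    pairs: tuple[tuple[float, float], ...]  # ordered, with multiplicity
    repetitions: int = 2

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def pool_size(self) -> int:
        return self.n_pairs * self.repetitions


def build_reduced_design(
    mid_levels: Sequence[float] = STUDY_MID_LEVELS,
    extremes: Sequence[float] = STUDY_EXTREMES,
    extreme_weight: int = 2,
    repetitions: int = 2,
) -> ReducedDesign:
    """Construct the reduced comparison multiset.

    Every mid level meets each extreme in both orders; the extreme-vs-extreme
    pair enters ``extreme_weight`` times each way (the study doubles it so the
    only direct low-vs-high comparison carries 4/20 of the weight instead of
    2/18).  The study configuration gives 8 + 8 + 2x2 = 20 pairs and a
    40-trial pool.
    """
    mids = tuple(float(v) for v in mid_levels)
    lo, hi = (float(v) for v in extremes)
    if set(mids) & {lo, hi}:
        raise ValueError("mid levels and extremes must not overlap")
    if extreme_weight < 1:
        raise ValueError("extreme_weight must be >= 1")
    pairs: list[tuple[float, float]] = []
    for m in mids:
        pairs += [(lo, m), (m, lo)]
    for m in mids:
        pairs += [(hi, m), (m, hi)]
    pairs += [(lo, hi), (hi, lo)] * extreme_weight
    levels = tuple(sorted({lo, hi, *mids}))
    return ReducedDesign(levels=levels, pairs=tuple(pairs), repetitions=repetitions)


def reduced_trial_pool(trials: Sequence[Trial], reduced: ReducedDesign) -> list[Trial]:
    """Select a participant's responses for the reduced design's pair multiset.

    Each (ordered pair, repetition) slot of the reduced design picks the
    matching full-design trial; a pair with multiplicity w > 1 reuses the same
    responses w times (distinct pool entries, as in "the data were used
    twice").  Returns ``reduced.pool_size`` trials.
    """
    index: dict[tuple[float, float, int], Trial] = {}
    for t in trials:
        index[(t.first, t.second, t.repetition)] = t
    pool: list[Trial] = []
    for pair in reduced.pairs:
        for rep in range(1, reduced.repetitions + 1):
            key = (pair[0], pair[1], rep)
            if key not in index:
                raise ValueError(
                    f"no response for pair {pair} repetition {rep} in the supplied trials"
                )
            pool.append(index[key])
    return pool


def restrict_centroids(centroids: dict, levels: Sequence[float]) -> dict[int, np.ndarray]:
    """Restrict full-design cluster centroids to the reduced level grid.

    A subsample can only inform the levels it contains, so distances are
    computed on a common support of reduced levels.
    """
    levels = tuple(float(v) for v in levels)
    out: dict[int, np.ndarray] = {}
    for c, info in centroids.items():
        grid = tuple(float(v) for v in info["levels"])
        idx = []
        for v in levels:
            if v not in grid:
                raise ValueError(f"centroid {c} has no value at level {v} dB")
            idx.append(grid.index(v))
        out[int(c)] = np.asarray(info["mean"], dtype=float)[idx]
    return out


def _profile_vector(
    drawn: Sequence[Trial], design: Design
) -> tuple[np.ndarray, np.ndarray]:
    """Win fractions of a draw plus a mask of levels that appeared."""
    wp = win_profile(drawn, design)
    frac = np.array(wp.fractions)
    mask = np.array([wp.appearances[v] > 0 for v in design.levels])
    return frac, mask


def subsample_classify(
    pool: Sequence[Trial],
    centroids: dict[int, np.ndarray],
    budget: int,
    replicates: int = 500,
    seed: int | np.random.Generator = 0,
) -> dict[int, float]:
    """Estimate cluster-assignment probabilities for one budget.

    Per replicate: draw ``budget`` trials uniformly without replacement from
    the pool, tally win fractions per reduced level, and assign to the
    nearest centroid by Euclidean distance over the levels that appeared in
    the draw (levels a draw never touched are excluded, not imputed — an
    imputed 0 would fabricate strong dispreference).  Exact distance ties
    split the assignment count equally.  Identical seeds give identical
    output.
    """
    pool = list(pool)
    if not (1 <= budget <= len(pool)):
        raise ValueError(f"budget {budget} outside [1, {len(pool)}]")
    cluster_ids = sorted(centroids)
    levels = tuple(sorted({lv for t in pool for lv in (t.first, t.second)}))
    design = Design(levels, repetitions=1)
    cvec = np.array([centroids[c] for c in cluster_ids], dtype=float)
    if cvec.shape[1] != len(levels):
        raise ValueError(
            f"centroids have {cvec.shape[1]} levels but the pool spans {len(levels)}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    counts = np.zeros(len(cluster_ids))
    pool_arr = np.arange(len(pool))
    for _ in range(replicates):
        draw_idx = rng.choice(pool_arr, size=budget, replace=False)
        frac, mask = _profile_vector([pool[i] for i in draw_idx], design)
        d2 = ((cvec[:, mask] - frac[mask]) ** 2).sum(axis=1)
        winners = np.flatnonzero(d2 <= d2.min() + 1e-12)
        counts[winners] += 1.0 / len(winners)
    probs = counts / replicates
    return {c: float(p) for c, p in zip(cluster_ids, probs)}


@dataclass
class BudgetCurve:
    """Probability of correct cluster versus comparison budget, one participant."""

    participant_id: str | None
    true_cluster: int
    budgets: tuple[int, ...]
    p_correct: tuple[float, ...]
    replicates: int
    seed: int


def budget_curve(
    pool: Sequence[Trial],
    centroids: dict[int, np.ndarray],
    true_cluster: int,
    budgets: Sequence[int] = tuple(range(5, 41, 5)),
    replicates: int = 500,
    seed: int = 0,
) -> BudgetCurve:
    """Probability-of-correct-cluster curve over a range of budgets.

    One seed governs the whole curve (a single numpy default_rng stream is
    consumed budget by budget), so identical inputs reproduce bit-identical
    curves.
    """
    if true_cluster not in centroids:
        raise ValueError(f"unknown true cluster {true_cluster!r}")
    rng = np.random.default_rng(seed)
    ps = []
    for n in budgets:
        probs = subsample_classify(pool, centroids, n, replicates=replicates, seed=rng)
        ps.append(probs[true_cluster])
    pid = pool[0].participant_id if pool else None
    return BudgetCurve(
        participant_id=pid,
        true_cluster=true_cluster,
        budgets=tuple(int(n) for n in budgets),
        p_correct=tuple(ps),
        replicates=replicates,
        seed=seed,
    )
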