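"""Synthetic cohorts with the statistical structure the analysis assumes.

No raw data accompany the study design this package analyses, so every
pipeline stage is exercised on generated cohorts that mirror it: three
hearing-status groups (normal hearing, mild loss, moderate loss) of ten
listeners, each completing the full 180-trial paired-comparison design, with
group-shifted preferred noise-reduction strengths (default medians 8.2 /
11.6 / 15.7 dB), concave quadratic utilities, and hearing-loss covariates
(better-ear PTA within group-consistent ranges, age and SRT positively
associated with PTA).

Choices are simulated from the same quadratic-utility-logistic model the
fitting stage estimates: a participant with true preference g* and curvature
b < 0 has a = -2*b*g*, and each trial is a Bernoulli draw with the model's
choice probability.  The recorded truth table makes parameter-recovery
checks exact.

`archetypes` builds the stylised three-cluster cohort (6 / 9 / 15 members
preferring none / intermediate / maximal noise reduction) used for
planted-partition recovery and the comparison-budget simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .qul_model import qul_utility
from .trial_design import (
    Design,
    ParticipantMeta,
    STUDY_DESIGN,
    Trial,
    WinProfile,
    enumerate_design,
    win_profile,
)

__all__ = [
    "GroupSpec",
    "CohortSpec",
    "Cohort",
    "ArchetypeCohort",
    "generate_cohort",
    "archetypes",
    "DEFAULT_SPEC",
]


@dataclass(frozen=True)
class GroupSpec:
    """One hearing-status group of the cohort.

    ``g_opt_median``/``g_opt_sd`` parameterise a normal for the preferred
    strength, truncated to the tested range; ``pta_range`` is the group's
    better-ear PTA interval in dB HL (NH <= 20, mild 20-40, moderate > 40).
    """

    name: str
    size: int
    g_opt_median: float
    g_opt_sd: float
    pta_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.size < 0:
            raise ValueError("group size must be >= 0")
        if self.g_opt_sd <= 0:
            raise ValueError("g_opt spread must be positive")
        lo, hi = self.pta_range
        if not lo < hi:
            raise ValueError("invalid PTA range")


@dataclass(frozen=True)
class CohortSpec:
    """Full cohort recipe: groups, curvature law, covariate model, design."""

    groups: tuple[GroupSpec, ...]
    b_range: tuple[float, float] = (-0.06, -0.01)
    design: Design = STUDY_DESIGN
    clamp: tuple[float, float] = (0.0, 18.0)
    # age = age_intercept + age_slope * PTA + N(0, age_noise_sd), years
    age_intercept: float = 30.0
    age_slope: float = 0.55
    age_noise_sd: float = 14.0
    # SRT = srt_intercept + srt_slope * PTA + N(0, srt_noise_sd), dB
    srt_intercept: float = 18.0
    srt_slope: float = 0.85
    srt_noise_sd: float = 7.0
    #: groups whose first members lack an SRT (5 NH listeners in the study)
    srt_missing: dict = field(default_factory=lambda: {"NH": 5})

    def __post_init__(self) -> None:
        b_lo, b_hi = self.b_range
        if not (b_lo < b_hi < 0):
            raise ValueError("curvature range must be negative (concave utility)")


DEFAULT_SPEC = CohortSpec(
    groups=(
        GroupSpec("NH", 10, 8.2, 3.8, (0.0, 20.0)),
        GroupSpec("HI-mild", 10, 11.6, 3.8, (20.0, 40.0)),
        GroupSpec("HI-moderate", 10, 15.7, 3.8, (40.0, 70.0)),
    )
)


@dataclass
class Cohort:
    """Generated trials, metadata, and the per-participant ground truth."""

    trials: list[Trial]
    metadata: list[ParticipantMeta]
    truth: list[dict]  # participant_id, group, a, b, g_opt (pre-clamp vertex)
    spec: CohortSpec

    def trials_of(self, pid: str) -> list[Trial]:
        return [t for t in self.trials if t.participant_id == pid]

    def profiles(self) -> list[WinProfile]:
        order = [m.participant_id for m in self.metadata]
        return [win_profile(self.trials_of(pid), self.spec.design) for pid in order]


def _participant_rng(master_seed: int, group_idx: int, member_idx: int) -> np.random.Generator:
    """Independent substream per participant, stable under group-size edits."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(group_idx, member_idx))
    return np.random.default_rng(ss)


def _draw_truncated_gopt(rng, median: float, sd: float, lo: float, hi: float) -> float:
    """Draw from a normal truncated to [lo, hi] whose *median* is ``median``.

    Truncation shifts the median away from the location parameter (markedly
    for groups near a bound), so the location is calibrated such that the
    truncated distribution's 50% point lands on the requested median.
    """
    from scipy.optimize import brentq

    def median_gap(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.ppf(0.5, a, b, loc=loc, scale=sd) - median

    loc = brentq(median_gap, lo - 6 * sd, hi + 6 * sd, xtol=1e-10)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return float(stats.truncnorm.rvs(a, b, loc=loc, scale=sd, random_state=rng))


def simulate_trials(
    pid: str, a: float, b: float, design: Design, rng: np.random.Generator
) -> list[Trial]:
    """Bernoulli-simulate every trial of the design under QUL coefficients."""
    templates = enumerate_design(design.levels, design.repetitions)
    g1 = np.array([t[0] for t in templates])
    g2 = np.array([t[1] for t in templates])
    from scipy.special import expit

    p_first = expit(qul_utility(a, b, g1) - qul_utility(a, b, g2))
    first_chosen = rng.random(len(templates)) < p_first
    return [
        Trial(pid, first, second, repetition=rep, choice="first" if win else "second")
        for (first, second, rep), win in zip(templates, first_chosen)
    ]


def generate_cohort(spec: CohortSpec = DEFAULT_SPEC, seed: int = 0) -> Cohort:
    """Generate a full synthetic cohort from a spec and master seed.

    Per participant: draw the true preferred strength g* from the group's
    truncated normal and the curvature b uniformly from ``b_range``, set
    a = -2*b*g* (so the utility vertex sits exactly at g*), simulate all
    design trials as Bernoulli QUL choices, then draw PTA uniformly in the
    group range and age/SRT as affine functions of PTA plus noise.  One
    master seed spawns per-participant substreams, so the same participant
    is reproduced even if other group sizes change.
    """
    lo, hi = spec.clamp
    trials: list[Trial] = []
    metadata: list[ParticipantMeta] = []
    truth: list[dict] = []
    for gi, grp in enumerate(spec.groups):
        for i in range(grp.size):
            rng = _participant_rng(seed, gi, i)
            pid = f"{grp.name}{i + 1}"
            g_star = _draw_truncated_gopt(rng, grp.g_opt_median, grp.g_opt_sd, lo, hi)
            b = float(rng.uniform(*spec.b_range))
            a = -2.0 * b * g_star
            trials.extend(simulate_trials(pid, a, b, spec.design, rng))
            pta = float(rng.uniform(*grp.pta_range))
            age = float(
                np.clip(
                    spec.age_intercept + spec.age_slope * pta + rng.normal(0, spec.age_noise_sd),
                    18.0,
                    95.0,
                )
            )
            n_missing = spec.srt_missing.get(grp.name, 0)
            if i < n_missing:
                srt = None
            else:
                srt = float(spec.srt_intercept + spec.srt_slope * pta + rng.normal(0, spec.srt_noise_sd))
            metadata.append(ParticipantMeta(pid, grp.name, pta, age, srt))
            truth.append({"participant_id": pid, "group": grp.name, "a": a, "b": b, "g_opt": g_star})
    return Cohort(trials=trials, metadata=metadata, truth=truth, spec=spec)


# ---------------------------------------------------------------------------
# Archetype cohort: three planted preference clusters
# ---------------------------------------------------------------------------

#: (label, count, a, b): utility coefficients of each archetype.  The
#: boundary preferrers use a steep linear term with near-zero curvature
#: (monotone utility => deterministic endpoint preference); the intermediate
#: archetype has its vertex at 10 dB with strong curvature.
ARCHETYPES = (
    ("no-NR", 6, -5.0, -1e-4),
    ("intermediate", 9, 10.0, -0.5),
    ("strong-NR", 15, 5.0, -1e-4),
)


@dataclass
class ArchetypeCohort:
    """Planted three-cluster cohort for recovery and budget experiments."""

    profiles: list[WinProfile]
    labels: np.ndarray  # planted cluster index per participant (0, 1, 2)
    trials: dict[str, list[Trial]]
    params: dict[str, tuple[float, float]]  # pid -> (a, b)
    design: Design


def archetypes(
    noise_sd: float = 0.0,
    seed: int = 0,
    design: Design = STUDY_DESIGN,
) -> ArchetypeCohort:
    """Build the stylised 6/9/15 three-cluster cohort.

    Responders are deterministic utility maximisers (equal utilities —
    levels equidistant from the intermediate vertex — fall back to the first
    presentation, which the balanced AB/BA design turns into a 0.5 win
    fraction).  ``noise_sd`` adds independent Gaussian noise (win-fraction
    units) to each level of each profile, clipped to [0, 1]; the trial
    records themselves stay deterministic.  Planted labels are returned for
    recovery scoring.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    profiles: list[WinProfile] = []
    labels: list[int] = []
    trials: dict[str, list[Trial]] = {}
    params: dict[str, tuple[float, float]] = {}
    templates = enumerate_design(design.levels, design.repetitions)
    for ci, (label, count, a, b) in enumerate(ARCHETYPES):
        for i in range(count):
            pid = f"{label}{i + 1}"
            ts = [
                Trial(
                    pid,
                    first,
                    second,
                    repetition=rep,
                    choice=(
                        "first"
                        if qul_utility(a, b, first) >= qul_utility(a, b, second)
                        else "second"
                    ),
                )
                for first, second, rep in templates
            ]
            wp = win_profile(ts, design)
            if noise_sd > 0:
                noisy = np.clip(
                    np.array(wp.fractions) + rng.normal(0, noise_sd, len(design.levels)),
                    0.0,
                    1.0,
                )
                appear = dict(wp.appearances)
                wp = WinProfile(
                    design.levels,
                    appear,
                    {
                        v: float(noisy[k] * appear[v])
                        for k, v in enumerate(design.levels)
                    },
                    participant_id=pid,
                )
            trials[pid] = ts
            params[pid] = (a, b)
            profiles.append(wp)
            labels.append(ci)
    return ArchetypeCohort(
        profiles=profiles,
        labels=np.array(labels),
        trials=trials,
        params=params,
        design=design,
    )
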