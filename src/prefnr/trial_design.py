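"""Paired-comparison experimental design, trial records, win counts, and I/O.

The experiment presents two speech-in-noise stimuli processed with different
noise-reduction strengths (the maximum gain reduction G_min, in dB) and asks
the listener which they prefer — a two-alternative forced choice with no tie
option.  The full study design crosses ten strengths
(0, 4, 6, 7, 8, 9, 10, 12, 16, 18 dB) in every ordered pair (AB and BA, to
balance presentation order), each pair twice, i.e. 10 x 9 x 2 = 180 trials
per participant.

Results are summarised per participant as a *win profile*: for each strength
level, in how many of the trials containing it was it chosen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import math

import pandas as pd

__all__ = [
    "STUDY_LEVELS",
    "STUDY_REPETITIONS",
    "Trial",
    "Design",
    "WinProfile",
    "ParticipantMeta",
    "InvalidDesignError",
    "TrialValidationError",
    "TrialParseError",
    "enumerate_design",
    "win_profile",
    "read_trials",
    "write_trials",
]

#: The strength grid used in the study (maximum gain reduction G_min, dB).
STUDY_LEVELS: tuple[float, ...] = (0, 4, 6, 7, 8, 9, 10, 12, 16, 18)

#: Test and retest of every ordered pair.
STUDY_REPETITIONS: int = 2


class InvalidDesignError(ValueError):
    """The level grid or repetition count cannot form a valid design."""


class TrialValidationError(ValueError):
    """A trial record violates the forced-choice data model."""


class TrialParseError(ValueError):
    """A trials file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class Trial:
    """One ordered paired-comparison presentation and its forced choice.

    ``choice`` is ``"first"`` or ``"second"`` — the listener must pick one of
    the two presented strengths; ties are not representable.
    """

    participant_id: str
    first: float
    second: float
    repetition: int = 1
    choice: str = "first"

    def __post_init__(self) -> None:
        object.__setattr__(self, "first", float(self.first))
        object.__setattr__(self, "second", float(self.second))
        if not (math.isfinite(self.first) and math.isfinite(self.second)):
            raise TrialValidationError("strength levels must be finite")
        if self.first == self.second:
            raise TrialValidationError(
                f"first and second stimulus must differ (both {self.first} dB)"
            )
        if self.choice not in ("first", "second"):
            raise TrialValidationError(
                f"choice must be 'first' or 'second', got {self.choice!r}"
            )
        if self.repetition < 1:
            raise TrialValidationError("repetition index must be >= 1")

    @property
    def chosen_level(self) -> float:
        return self.first if self.choice == "first" else self.second

    @property
    def rejected_level(self) -> float:
        return self.second if self.choice == "first" else self.first


@dataclass(frozen=True)
class Design:
    """A full round-robin paired-comparison design over a strength grid."""

    levels: tuple[float, ...]
    repetitions: int = 1

    def __post_init__(self) -> None:
        levels = tuple(float(v) for v in self.levels)
        if len(levels) < 2:
            raise InvalidDesignError("a design needs at least 2 strength levels")
        if len(set(levels)) != len(levels):
            raise InvalidDesignError(f"duplicate levels in design grid: {levels}")
        if any(v < 0 for v in levels):
            raise InvalidDesignError("strength levels (gain reductions) must be >= 0 dB")
        if list(levels) != sorted(levels):
            raise InvalidDesignError("design grid must be strictly increasing")
        if self.repetitions < 1:
            raise InvalidDesignError("repetitions must be >= 1")
        object.__setattr__(self, "levels", levels)

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def n_trials(self) -> int:
        """Trials per participant: L(L-1) ordered pairs times repetitions."""
        L = self.n_levels
        return L * (L - 1) * self.repetitions

    @property
    def appearances_per_level(self) -> int:
        """Each level meets every other level in both orders, every repetition."""
        return 2 * (self.n_levels - 1) * self.repetitions


#: The 10-level, 2-repetition design of the study (180 trials/participant).
STUDY_DESIGN = Design(STUDY_LEVELS, STUDY_REPETITIONS)


def enumerate_design(
    levels: Sequence[float], repetitions: int = 1
) -> list[tuple[float, float, int]]:
    """Enumerate every ordered trial template of a round-robin design.

    Returns ``(first, second, repetition)`` tuples in canonical lexicographic
    order by (first level, second level, repetition).  Presentation-order
    randomisation is deliberately left to the caller (with their own seeded
    RNG); the enumerator itself is deterministic.

    >>> len(enumerate_design((0, 4, 6, 7, 8, 9, 10, 12, 16, 18), 2))
    180
    """
    design = Design(tuple(levels), repetitions)
    templates = [
        (a, b, r)
        for a in design.levels
        for b in design.levels
        if a != b
        for r in range(1, repetitions + 1)
    ]
    return templates


@dataclass
class WinProfile:
    """Per-level appearance and win counts for one participant.

    ``win_fraction`` for a level is wins/appearances, i.e. the fraction of
    trials containing the level in which it was chosen.  Levels with zero
    appearances (possible on subsampled data) carry ``nan`` — an undefined
    fraction, deliberately not 0, so it cannot masquerade as dispreference.
    """

    levels: tuple[float, ...]
    appearances: dict[float, int]
    wins: dict[float, int]
    participant_id: str | None = None

    def win_fraction(self, level: float) -> float:
        n = self.appearances[level]
        if n == 0:
            return float("nan")
        return self.wins[level] / n

    @property
    def fractions(self) -> list[float]:
        """Win fractions in level order (nan where a level never appeared)."""
        return [self.win_fraction(v) for v in self.levels]

    @property
    def total_wins(self) -> int:
        return sum(self.wins.values())


def win_profile(trials: Iterable[Trial], design: Design) -> WinProfile:
    """Tally per-level appearances and wins for one participant's trials.

    Works on any subset of a participant's trials (the comparison-budget
    resampler relies on this); each trial contributes one appearance to both
    of its levels and one win to the chosen level.
    """
    trials = list(trials)
    if not trials:
        raise TrialValidationError("cannot build a win profile from zero trials")
    grid = set(design.levels)
    appearances = {v: 0 for v in design.levels}
    wins = {v: 0 for v in design.levels}
    pid = trials[0].participant_id
    for t in trials:
        for lev in (t.first, t.second):
            if lev not in grid:
                raise TrialValidationError(
                    f"trial level {lev} dB is not on the design grid {design.levels}"
                )
        appearances[t.first] += 1
        appearances[t.second] += 1
        wins[t.chosen_level] += 1
    return WinProfile(design.levels, appearances, wins, participant_id=pid)


@dataclass(frozen=True)
class ParticipantMeta:
    """Participant covariates: hearing-loss group, better-ear PTA, age, SRT.

    PTA is the pure-tone average at 1, 2, 4 kHz of the better ear (dB HL);
    the better ear is the one with the lower PTA.  SRT (speech reception
    threshold for CVC words in quiet, dB) may be absent.
    """

    participant_id: str
    group: str
    pta_better: float
    age: float
    srt: float | None = None

    GROUPS = ("NH", "HI-mild", "HI-moderate")

    def __post_init__(self) -> None:
        if self.group not in self.GROUPS:
            raise TrialValidationError(
                f"unknown hearing-loss group {self.group!r}; expected one of {self.GROUPS}"
            )


TRIAL_COLUMNS = ["participant_id", "group", "repetition", "first_db", "second_db", "choice"]
META_COLUMNS = ["participant_id", "group", "pta_better_db_hl", "age_years", "srt_db"]


def write_trials(
    trials: Sequence[Trial],
    metadata: Sequence[ParticipantMeta],
    trials_path,
    meta_path=None,
) -> None:
    """Write trials (and optionally metadata) as UTF-8 CSV with header rows."""
    group_of = {m.participant_id: m.group for m in metadata}
    df = pd.DataFrame(
        {
            "participant_id": [t.participant_id for t in trials],
            "group": [group_of.get(t.participant_id, "") for t in trials],
            "repetition": [t.repetition for t in trials],
            "first_db": [t.first for t in trials],
            "second_db": [t.second for t in trials],
            "choice": [t.choice for t in trials],
        }
    )
    df.to_csv(trials_path, index=False)
    if meta_path is not None:
        mdf = pd.DataFrame(
            {
                "participant_id": [m.participant_id for m in metadata],
                "group": [m.group for m in metadata],
                "pta_better_db_hl": [m.pta_better for m in metadata],
                "age_years": [m.age for m in metadata],
                "srt_db": [m.srt if m.srt is not None else "" for m in metadata],
            }
        )
        mdf.to_csv(meta_path, index=False)


def read_trials(
    trials_path, meta_path=None, strict_columns: bool = False
) -> tuple[list[Trial], list[ParticipantMeta]]:
    """Read trials (and optional metadata) CSV files.

    Unknown columns are ignored by default; with ``strict_columns`` they raise.
    Malformed rows raise :class:`TrialParseError` with the 1-based file line
    number (header is line 1).
    """
    df = pd.read_csv(trials_path, dtype=str, keep_default_na=False)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns and c != "group"]
    if missing:
        raise TrialParseError(f"missing mandatory column(s): {', '.join(missing)}")
    if strict_columns:
        extra = [c for c in df.columns if c not in TRIAL_COLUMNS]
        if extra:
            raise TrialParseError(f"unexpected column(s): {', '.join(extra)}")

    trials: list[Trial] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header occupies line 1
        choice = row["choice"].strip()
        if choice not in ("first", "second"):
            raise TrialParseError(
                f"choice must be 'first' or 'second', got {choice!r}", line=line
            )
        try:
            first = float(row["first_db"])
            second = float(row["second_db"])
            rep = int(row["repetition"])
        except ValueError as exc:
            raise TrialParseError(f"non-numeric field: {exc}", line=line) from None
        try:
            trials.append(
                Trial(
                    participant_id=row["participant_id"],
                    first=first,
                    second=second,
                    repetition=rep,
                    choice=choice,
                )
            )
        except TrialValidationError as exc:
            raise TrialParseError(str(exc), line=line) from None

    metadata: list[ParticipantMeta] = []
    if meta_path is not None:
        mdf = pd.read_csv(meta_path, dtype=str, keep_default_na=False)
        mmissing = [c for c in META_COLUMNS if c not in mdf.columns]
        if mmissing:
            raise TrialParseError(f"missing metadata column(s): {', '.join(mmissing)}")
        for idx, row in mdf.iterrows():
            line = idx + 2
            srt_raw = row["srt_db"].strip()
            try:
                metadata.append(
                    ParticipantMeta(
                        participant_id=row["participant_id"],
                        group=row["group"],
                        pta_better=float(row["pta_better_db_hl"]),
                        age=float(row["age_years"]),
                        srt=float(srt_raw) if srt_raw else None,
                    )
                )
            except (ValueError, TrialValidationError) as exc:
                raise TrialParseError(str(exc), line=line) from None
    return trials, metadata
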