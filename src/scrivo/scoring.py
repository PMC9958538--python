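"""BVSCO-2 handwriting-speed scoring, normative risk labeling, and SUS.

The BVSCO-2 speed battery has three one-minute exercises (writing "le" in
cursive, writing "uno", writing number words); each is scored as graphemes
written per minute.  A child is *under threshold* on an exercise when the
count falls strictly below the grade's normative mean minus two standard
deviations, and *at risk* when under threshold in at least one exercise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

GRADES = (1, 2, 3)
EXERCISES = (1, 2, 3)


class ConfigurationError(ValueError):
    """A normative table or spec field is missing or inconsistent."""


class ValidationError(ValueError):
    """Raised for out-of-contract questionnaire or score inputs."""


@dataclass(frozen=True)
class BVSCOResult:
    """Grapheme-per-minute counts for the three speed exercises."""

    grade: int
    counts: tuple  # three non-negative ints

    def __post_init__(self) -> None:
        if self.grade not in GRADES:
            raise ValidationError(f"grade must be in {GRADES}, got {self.grade}")
        if len(self.counts) != 3 or any(c < 0 for c in self.counts):
            raise ValidationError("counts must be three non-negative integers")


@dataclass(frozen=True)
class RiskLabel:
    """Per-exercise under-threshold flags and the derived dichotomy."""

    per_exercise: tuple  # three bools
    at_risk: bool

    def __post_init__(self) -> None:
        if self.at_risk != any(self.per_exercise):
            raise ValidationError("at_risk must be the OR of the per-exercise flags")


class NormativeTable:
    """Grade x exercise normative means and SDs (graphemes per minute).

    The published normative data are copyrighted and not shipped; the
    default table is synthetic, with plausible ordering across grades.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"grade", "exercise", "mean", "sd"}
        if not required.issubset(table.columns):
            raise ConfigurationError(f"norms need columns {sorted(required)}")
        t = table[["grade", "exercise", "mean", "sd"]].copy()
        t["grade"] = t["grade"].astype(int)
        t["exercise"] = t["exercise"].astype(int)
        idx = set(zip(t["grade"], t["exercise"]))
        expected = {(g, e) for g in GRADES for e in EXERCISES}
        if idx != expected:
            raise ConfigurationError("norms must cover the full 3x3 grade/exercise grid")
        if (t["sd"] <= 0).any():
            raise ConfigurationError("normative SDs must be positive")
        self._table = t.set_index(["grade", "exercise"]).sort_index()

    @classmethod
    def default_synthetic(cls) -> "NormativeTable":
        rows = [
            {"grade": g, "exercise": e, "mean": 20.0 + 10.0 * g, "sd": 8.0}
            for g in GRADES
            for e in EXERCISES
        ]
        return cls(pd.DataFrame(rows))

    @classmethod
    def from_csv(cls, path) -> "NormativeTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_frame(self) -> pd.DataFrame:
        return self._table.reset_index()

    def mean(self, grade: int, exercise: int) -> float:
        return float(self._row(grade, exercise)["mean"])

    def sd(self, grade: int, exercise: int) -> float:
        return float(self._row(grade, exercise)["sd"])

    def threshold(self, grade: int, exercise: int) -> float:
        """Under-threshold cutoff: normative mean minus two SDs."""
        row = self._row(grade, exercise)
        return float(row["mean"] - 2.0 * row["sd"])

    def _row(self, grade: int, exercise: int) -> pd.Series:
        try:
            return self._table.loc[(int(grade), int(exercise))]
        except KeyError:
            raise ConfigurationError(
                f"no normative row for grade={grade}, exercise={exercise}"
            ) from None


def count_le_graphemes(transcript: str) -> int:
    """Count graphemes in a 'le' transcript, excluding sequence breaks.

    A greedy left-to-right scan finds non-overlapping "le" bigrams;
    characters that break the alternation are skipped and excluded from the
    count.  Each matched bigram contributes two graphemes.  Characters
    outside {l, e} are excluded with a warning.
    """
    s = "".join(transcript.split()).lower()
    foreign = sum(1 for ch in s if ch not in ("l", "e"))
    if foreign:
        warnings.warn(
            f"{foreign} character(s) outside the 'le' alphabet excluded", stacklevel=2
        )
        s = "".join(ch for ch in s if ch in ("l", "e"))
    bigrams = 0
    i = 0
    while i < len(s) - 1:
        if s[i] == "l" and s[i + 1] == "e":
            bigrams += 1
            i += 2
        else:
            i += 1
    return 2 * bigrams


def threshold_and_label(result: BVSCOResult, norms: NormativeTable) -> RiskLabel:
    """Apply the normative under-threshold rule and derive the risk label.

    A count exactly equal to mean - 2*SD is over threshold (the rule is a
    strict 'lower than').
    """
    flags = tuple(
        result.counts[e - 1] < norms.threshold(result.grade, e) for e in EXERCISES
    )
    return RiskLabel(per_exercise=flags, at_risk=any(flags))


def label_cohort(bvsco: pd.DataFrame, norms: NormativeTable) -> pd.DataFrame:
    """Label a cohort table (subject_id, grade, c1, c2, c3) -> labels frame."""
    rows = []
    for _, r in bvsco.iterrows():
        lab = threshold_and_label(
            BVSCOResult(int(r["grade"]), (int(r["c1"]), int(r["c2"]), int(r["c3"]))), norms
        )
        rows.append(
            {
                "subject_id": r["subject_id"],
                "under_1": lab.per_exercise[0],
                "under_2": lab.per_exercise[1],
                "under_3": lab.per_exercise[2],
                "n_over_threshold": 3 - sum(lab.per_exercise),
                "at_risk": lab.at_risk,
            }
        )
    return pd.DataFrame(rows)


def sus_score(responses) -> float:
    """Transform ten 1-5 SUS item responses into the 0-100 usability score.

    Odd-numbered items (1-based) contribute (response - 1), even-numbered
    items (5 - response); the sum is multiplied by 2.5.
    """
    responses = list(responses)
    if len(responses) != 10:
        raise ValidationError(f"SUS needs exactly 10 responses, got {len(responses)}")
    total = 0
    for i, r in enumerate(responses, start=1):
        if not (isinstance(r, (int, np.integer)) and 1 <= r <= 5):
            raise ValidationError(f"SUS item {i} response {r!r} not an integer in 1..5")
        total += (r - 1) if i % 2 == 1 else (5 - r)
    return 2.5 * total
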