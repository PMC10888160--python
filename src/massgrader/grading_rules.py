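"""Mass-to-grade mapping and grading-outcome statistics.

Grades follow the Shandong provincial cucumber standard DB37/T564-2005:
grade 1 is the premium band 150-170 g (both ends included), grade 2 is
(170, 250] g, and grade 3 is everything else — undersized (< 150 g) or
oversized (> 250 g) fruit. The overall grading efficiency of a sorting run
is the percentage of items that were not misgraded,

    eta0 = (T_N - T_M) / T_N * 100,

with T_N the total number of items tested and T_M the number misgraded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "GradeThresholds",
    "GradingOutcome",
    "assign_grade",
    "grading_efficiency",
    "tabulate_outcome",
    "GRADES",
]

GRADES = (1, 2, 3)


@dataclass(frozen=True)
class GradeThresholds:
    """Mass boundaries (grams) separating the three grades.

    ``g1_low <= mass <= g1_high`` is grade 1; ``g1_high < mass <= g2_high``
    is grade 2; the complement is grade 3.
    """

    g1_low: float = 150.0
    g1_high: float = 170.0
    g2_high: float = 250.0

    def __post_init__(self):
        if not (self.g1_low < self.g1_high < self.g2_high):
            raise ValueError(
                f"thresholds must be ordered g1_low < g1_high < g2_high, "
                f"got {self.g1_low}, {self.g1_high}, {self.g2_high}"
            )


@dataclass
class GradingOutcome:
    """Per-grade tested/missed counts plus the overall efficiency."""

    per_grade_tested: dict[int, int]
    per_grade_missed: dict[int, int]
    t_n: int
    t_m: int
    eta0: float

    def as_rows(self) -> list[dict]:
        return [
            {
                "grade": g,
                "tested": self.per_grade_tested[g],
                "missed": self.per_grade_missed[g],
            }
            for g in GRADES
        ]


def assign_grade(mass: float, thresholds: GradeThresholds | None = None) -> int:
    """Map a single-cucumber mass (g) to a grade in {1, 2, 3}."""
    t = thresholds or GradeThresholds()
    if not mass > 0:
        raise ValueError(f"mass must be positive, got {mass}")
    if t.g1_low <= mass <= t.g1_high:
        return 1
    if t.g1_high < mass <= t.g2_high:
        return 2
    return 3


def grading_efficiency(t_n: int, t_m: int) -> float:
    """Overall grading efficiency eta0 in percent."""
    if t_n < 1:
        raise ValueError("t_n must be at least 1")
    if not 0 <= t_m <= t_n:
        raise ValueError(f"t_m must satisfy 0 <= t_m <= t_n, got {t_m} of {t_n}")
    return (t_n - t_m) / t_n * 100.0


def tabulate_outcome(
    true_grades: Sequence[int], routed_grades: Sequence[int]
) -> GradingOutcome:
    """Tabulate a grading run: counts per true grade, misses per true grade.

    A miss is any item whose routed grade differs from its true grade; it is
    attributed to the row of the true grade.
    """
    if len(true_grades) != len(routed_grades):
        raise ValueError(
            f"length mismatch: {len(true_grades)} true vs {len(routed_grades)} routed"
        )
    tested = {g: 0 for g in GRADES}
    missed = {g: 0 for g in GRADES}
    for t, r in zip(true_grades, routed_grades):
        if t not in tested:
            raise ValueError(f"invalid true grade {t}")
        tested[t] += 1
        if r != t:
            missed[t] += 1
    t_n = sum(tested.values())
    t_m = sum(missed.values())
    return GradingOutcome(tested, missed, t_n, t_m, grading_efficiency(t_n, t_m))
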