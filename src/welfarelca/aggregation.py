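"""Welfare Quality (WQ) score aggregation.

Combines the four WQ principle scores of the two production stages
(sows-and-piglets, SP; fattening pigs, FP) into a single overall score by
weighting each stage's principle-weighted score with the proportion of
life-years that stage contributes per finished pig.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterator

from welfarelca.errors import NormalizationError

#: Canonical principle order used everywhere in the package.
PRINCIPLES = ("health", "feeding", "behaviour", "housing")

#: Differences of at most this many score points are not considered
#: biologically meaningful (reporting metadata; never alters statistics).
INDIFFERENCE_THRESHOLD = 5.0


@dataclass(frozen=True)
class WQAssessment:
    """Four WQ principle scores (0-100, 100 = best welfare) for one stage."""

    p_health: float
    p_feeding: float
    p_behaviour: float
    p_housing: float

    def validate(self) -> list[str]:
        """Range violations (empty = valid); construction is deliberately
        lenient so whole populations can be validated in one pass."""
        return [
            f"p_{name}: score {value!r} outside [0, 100]"
            for name, value in zip(PRINCIPLES, self.scores)
            if not (0.0 <= value <= 100.0)
        ]

    @property
    def scores(self) -> tuple[float, float, float, float]:
        """Scores in canonical principle order."""
        return (self.p_health, self.p_feeding, self.p_behaviour, self.p_housing)

    def __iter__(self) -> Iterator[float]:
        return iter(self.scores)


@dataclass(frozen=True)
class PrincipleWeighting:
    """Normalized principle weights (health, feeding, behaviour, housing)."""

    w_health: float
    w_feeding: float
    w_behaviour: float
    w_housing: float
    name: str = "custom"

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights):
            raise ValueError("principle weights must be non-negative")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise NormalizationError(
                f"principle weights must sum to 1, got {sum(self.weights)!r}"
            )

    @property
    def weights(self) -> tuple[float, float, float, float]:
        return (self.w_health, self.w_feeding, self.w_behaviour, self.w_housing)


#: The three published weighting schemes. ``standard`` emphasises health,
#: ``equal`` removes that emphasis, ``extreme`` doubles down on it.
STANDARD_WEIGHTING = PrincipleWeighting(0.35, 0.25, 0.25, 0.15, name="standard")
EQUAL_WEIGHTING = PrincipleWeighting(0.25, 0.25, 0.25, 0.25, name="equal")
EXTREME_WEIGHTING = PrincipleWeighting(0.50, 0.20, 0.20, 0.10, name="extreme")

WEIGHTING_PRESETS: dict[str, PrincipleWeighting] = {
    "standard": STANDARD_WEIGHTING,
    "equal": EQUAL_WEIGHTING,
    "extreme": EXTREME_WEIGHTING,
}


class ClassificationLevel(str, Enum):
    """WQ farm classification levels (ordered: excellent > enhanced > neither)."""

    EXCELLENT = "excellent"
    ENHANCED = "enhanced"
    NEITHER = "neither"


@dataclass(frozen=True)
class WQClassification:
    level: ClassificationLevel = ClassificationLevel.NEITHER

    def meets(self, level: ClassificationLevel) -> bool:
        """True if this classification is at least as good as *level*."""
        order = {
            ClassificationLevel.NEITHER: 0,
            ClassificationLevel.ENHANCED: 1,
            ClassificationLevel.EXCELLENT: 2,
        }
        return order[self.level] >= order[level]


def weighted_stage_score(a: WQAssessment, w: PrincipleWeighting) -> float:
    """Weighted mean of the four principle scores of one stage.

    Returns a value in [min(p), max(p)] since the weights are a convex
    combination.
    """
    return math.fsum(p * wi for p, wi in zip(a.scores, w.weights))


def overall_wq_score(
    a_SP: WQAssessment,
    a_FP: WQAssessment,
    w: PrincipleWeighting,
    t_SP: float,
    t_FP: float,
    *,
    w_FP: PrincipleWeighting | None = None,
) -> float:
    """Overall WQ score of a breed-to-finish system.

    Each stage's weighted score is multiplied by the proportion of
    life-years (``t_SP``, ``t_FP``) that stage requires per finished pig.
    A separate fattening-stage weighting can be supplied via ``w_FP`` for
    sensitivity work; by default both stages use the same scheme.

    Raises
    ------
    NormalizationError
        If the stage proportions do not sum to one.
    """
    if abs(t_SP + t_FP - 1.0) > 1e-9:
        raise NormalizationError(
            f"stage proportions must sum to 1, got t_SP={t_SP!r}, t_FP={t_FP!r}"
        )
    w_fp = w if w_FP is None else w_FP
    return t_SP * weighted_stage_score(a_SP, w) + t_FP * weighted_stage_score(
        a_FP, w_fp
    )


def classify(a: WQAssessment) -> WQClassification:
    """Classify a stage assessment as excellent / enhanced / neither.

    excellent: all four principles >= 55 and at least two >= 80;
    enhanced:  all four principles >= 20 and at least two >= 55.
    Excellent implies the enhanced conditions.
    """
    scores = a.scores
    if min(scores) >= 55 and sum(s >= 80 for s in scores) >= 2:
        return WQClassification(ClassificationLevel.EXCELLENT)
    if min(scores) >= 20 and sum(s >= 55 for s in scores) >= 2:
        return WQClassification(ClassificationLevel.ENHANCED)
    return WQClassification(ClassificationLevel.NEITHER)


def biologically_different(s1: float, s2: float) -> bool:
    """True iff two WQ scores differ by more than the indifference threshold."""
    for s in (s1, s2):
        if not (0.0 <= s <= 100.0):
            raise ValueError(f"score {s!r} outside [0, 100]")
    return abs(s1 - s2) > INDIFFERENCE_THRESHOLD
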