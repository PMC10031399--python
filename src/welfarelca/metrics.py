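"""The welfare-cost metric family.

A welfare cost is a sum over 4 principles x 2 stages.  Each term is either
a cost, ``(100 - p) * w * y``, or a benefit, ``-p * w * y``, depending on
whether the principle score meets the metric's cost-to-benefit transition.
``y`` is the stage's life-years per kg deadweight, so costs are expressed
per kg DW and scale linearly with the functional unit.  Higher values mean
poorer welfare; negative values are net welfare benefits.

The canonical grid has 30 variants: transitions
{T=100, 90, 80, 70, 60, 50, 40, excellent, enhanced, behaviour} crossed
with the three principle weightings {standard, equal, extreme}.

Note the benefit branch makes each term discontinuous at ``p == T`` (the
contribution drops from ``(100 - T) w y`` to ``-T w y``); this is
implemented exactly as defined, with no smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from welfarelca.aggregation import (
    ClassificationLevel,
    PrincipleWeighting,
    WEIGHTING_PRESETS,
    WQAssessment,
    classify,
)
from welfarelca.domain import BreedToFinishSystem
from welfarelca.errors import ConfigurationError
from welfarelca.production import LifeYearsProfile, life_years_per_kg

#: Numeric transitions of the canonical grid, in presentation order.
CANONICAL_THRESHOLDS = (100.0, 90.0, 80.0, 70.0, 60.0, 50.0, 40.0)


class TransitionKind(str, Enum):
    NUMERIC = "numeric"
    CLASSIFICATION = "classification"
    BEHAVIOUR_BENEFIT = "behaviour_benefit"


@dataclass(frozen=True)
class TransitionSpec:
    """The rule deciding which principle-stage terms count as benefits.

    numeric: a principle's life-time is a benefit iff its score >= threshold,
    per principle and stage independently.
    classification: all four principles of a stage flip to benefits iff that
    stage's assessment meets the given WQ classification (excellent counts
    as meeting enhanced), evaluated per stage.
    behaviour_benefit: appropriate behaviour is always a benefit, the other
    three principles always costs, in both stages (no threshold involved).
    """

    kind: TransitionKind
    threshold: float | None = None
    classification_level: ClassificationLevel | None = None

    def __post_init__(self) -> None:
        if self.kind is TransitionKind.NUMERIC:
            if self.threshold is None or self.classification_level is not None:
                raise ConfigurationError(
                    "numeric transition requires threshold only"
                )
            if not (0.0 <= self.threshold <= 100.0):
                raise ConfigurationError(
                    f"threshold {self.threshold!r} outside [0, 100]"
                )
        elif self.kind is TransitionKind.CLASSIFICATION:
            if self.classification_level is None or self.threshold is not None:
                raise ConfigurationError(
                    "classification transition requires classification_level only"
                )
            if self.classification_level is ClassificationLevel.NEITHER:
                raise ConfigurationError(
                    "classification transition level must be excellent or enhanced"
                )
        elif self.kind is TransitionKind.BEHAVIOUR_BENEFIT:
            if self.threshold is not None or self.classification_level is not None:
                raise ConfigurationError(
                    "behaviour_benefit transition takes no parameters"
                )

    @classmethod
    def numeric(cls, threshold: float) -> "TransitionSpec":
        return cls(TransitionKind.NUMERIC, threshold=threshold)

    @classmethod
    def classification(cls, level: ClassificationLevel | str) -> "TransitionSpec":
        return cls(
            TransitionKind.CLASSIFICATION,
            classification_level=ClassificationLevel(level),
        )

    @classmethod
    def behaviour_benefit(cls) -> "TransitionSpec":
        return cls(TransitionKind.BEHAVIOUR_BENEFIT)

    @property
    def tag(self) -> str:
        if self.kind is TransitionKind.NUMERIC:
            return f"T{self.threshold:g}"
        if self.kind is TransitionKind.CLASSIFICATION:
            return self.classification_level.value
        return "behaviour"


@dataclass(frozen=True)
class MetricSpec:
    """One transition rule paired with one principle weighting."""

    transition: TransitionSpec
    weighting: PrincipleWeighting

    @property
    def metric_id(self) -> str:
        return f"{self.transition.tag}/{self.weighting.name}"


@dataclass(frozen=True)
class WelfareCostResult:
    """Welfare cost of one system under one metric, with stage subtotals."""

    system_id: str
    metric_id: str
    cost: float
    sp_component: float
    fp_component: float


def canonical_grid(
    weightings: Sequence[str] = ("standard", "equal", "extreme"),
) -> list[MetricSpec]:
    """The 30-variant metric grid (10 transitions x 3 weightings)."""
    transitions = [TransitionSpec.numeric(t) for t in CANONICAL_THRESHOLDS]
    transitions.append(TransitionSpec.classification(ClassificationLevel.EXCELLENT))
    transitions.append(TransitionSpec.classification(ClassificationLevel.ENHANCED))
    transitions.append(TransitionSpec.behaviour_benefit())
    return [
        MetricSpec(transition=tr, weighting=WEIGHTING_PRESETS[w])
        for tr in transitions
        for w in weightings
    ]


def resolve_benefit_flags(
    a_SP: WQAssessment,
    a_FP: WQAssessment,
    transition: TransitionSpec,
) -> tuple[tuple[bool, bool, bool, bool], tuple[bool, bool, bool, bool]]:
    """Per-stage, per-principle booleans: True = benefit branch applies."""
    if transition.kind is TransitionKind.NUMERIC:
        thr = transition.threshold
        return (
            tuple(p >= thr for p in a_SP.scores),
            tuple(p >= thr for p in a_FP.scores),
        )
    if transition.kind is TransitionKind.CLASSIFICATION:
        level = transition.classification_level
        sp_meets = classify(a_SP).meets(level)
        fp_meets = classify(a_FP).meets(level)
        return ((sp_meets,) * 4, (fp_meets,) * 4)
    # behaviour_benefit: behaviour (index 2) only, both stages
    flags = (False, False, True, False)
    return (flags, flags)


def principle_contribution(
    p: float, w: float, y: float, is_benefit: bool
) -> float:
    """One principle-stage term: ``(100 - p) w y`` as cost, ``-p w y`` as benefit."""
    if is_benefit:
        return -p * w * y
    return (100.0 - p) * w * y


def welfare_cost(
    a_SP: WQAssessment,
    a_FP: WQAssessment,
    spec: MetricSpec,
    y: LifeYearsProfile,
) -> WelfareCostResult:
    """Welfare cost per kg DW of one system under one metric variant."""
    sp_flags, fp_flags = resolve_benefit_flags(a_SP, a_FP, spec.transition)
    weights = spec.weighting.weights
    sp_total = 0.0
    fp_total = 0.0
    for p, w, flag in zip(a_SP.scores, weights, sp_flags):
        sp_total += principle_contribution(p, w, y.y_SP, flag)
    for p, w, flag in zip(a_FP.scores, weights, fp_flags):
        fp_total += principle_contribution(p, w, y.y_FP, flag)
    return WelfareCostResult(
        system_id="",
        metric_id=spec.metric_id,
        cost=sp_total + fp_total,
        sp_component=sp_total,
        fp_component=fp_total,
    )


def metric_grid(
    systems: Iterable[BreedToFinishSystem],
    specs: Sequence[MetricSpec] | None = None,
) -> pd.DataFrame:
    """Welfare costs for every system under every metric variant.

    Returns a tidy table with one row per system x metric, sorted by
    (system_id, metric_id), with columns ``system_id``, ``metric_id``,
    ``transition``, ``weighting``, ``cost``, ``sp_component``,
    ``fp_component``.
    """
    if specs is None:
        specs = canonical_grid()
    if not specs:
        raise ConfigurationError("metric grid requires at least one MetricSpec")
    ids = [s.metric_id for s in specs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ConfigurationError(f"duplicate metric_id(s): {dupes}")

    rows = []
    for system in systems:
        profile = life_years_per_kg(system.production)
        for spec in specs:
            result = welfare_cost(
                system.assessment_SP, system.assessment_FP, spec, profile
            )
            rows.append(
                {
                    "system_id": system.system_id,
                    "metric_id": spec.metric_id,
                    "transition": spec.transition.tag,
                    "weighting": spec.weighting.name,
                    "cost": result.cost,
                    "sp_component": result.sp_component,
                    "fp_component": result.fp_component,
                }
            )
    frame = pd.DataFrame(
        rows,
        columns=[
            "system_id",
            "metric_id",
            "transition",
            "weighting",
            "cost",
            "sp_component",
            "fp_component",
        ],
    )
    return frame.sort_values(["system_id", "metric_id"], kind="mergesort").reset_index(
        drop=True
    )
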