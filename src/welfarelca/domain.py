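"""Shared data model: label types, husbandry types, breed-to-finish systems.

Label and husbandry vocabularies are closed; free text must be normalized
upstream (see :mod:`welfarelca.io`) before entering the domain model.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional

from welfarelca.aggregation import WQAssessment
from welfarelca.errors import VocabularyError
from welfarelca.production import ProductionRecord


class LabelType(Enum):
    """Assurance-scheme / marketing categories, ordered least to most demanding.

    The integer value is the precedence rank.  Quality Meat Scotland is
    treated as ``RED_TRACTOR`` (same tier of standards).
    """

    NONE = 0
    RED_TRACTOR = 1
    RSPCA_ASSURED = 2
    FREE_RANGE = 3
    WOODLAND = 4
    ORGANIC = 5

    @property
    def label(self) -> str:
        return self.name.lower()

    @property
    def rank(self) -> int:
        return self.value

    @classmethod
    def from_name(cls, name: str) -> "LabelType":
        try:
            return cls[name.upper()]
        except KeyError:
            raise VocabularyError(
                f"unknown label type {name!r}; expected one of "
                f"{[m.label for m in cls]}"
            ) from None


#: Reporting order for label types, least to most demanding.
LABEL_ORDER = tuple(LabelType)

BREEDING_HUSBANDRY = ("indoor", "hybrid", "outdoor")
FINISHING_HUSBANDRY = ("slatted", "straw_yard", "outdoor")


@dataclass(frozen=True)
class HusbandryType:
    """Breeding and finishing husbandry, each from a closed vocabulary."""

    breeding: str
    finishing: str

    def __post_init__(self) -> None:
        if self.breeding not in BREEDING_HUSBANDRY:
            raise VocabularyError(
                f"unknown breeding husbandry {self.breeding!r}; expected one of "
                f"{list(BREEDING_HUSBANDRY)}"
            )
        if self.finishing not in FINISHING_HUSBANDRY:
            raise VocabularyError(
                f"unknown finishing husbandry {self.finishing!r}; expected one "
                f"of {list(FINISHING_HUSBANDRY)}"
            )


def assign_label_type(labels_held: Iterable[str]) -> LabelType:
    """The most demanding label among those held; ``NONE`` for an empty set.

    Idempotent and order-independent; raises :class:`VocabularyError` for
    unknown label names.
    """
    members = [LabelType.from_name(name) for name in set(labels_held)]
    if not members:
        return LabelType.NONE
    return max(members, key=lambda m: m.rank)


@dataclass(frozen=True)
class BreedToFinishSystem:
    """One breed-to-finish pig system: labels, husbandry, WQ scores, production."""

    system_id: str
    labels_held: frozenset[str]
    assigned_label: LabelType
    husbandry: HusbandryType
    assessment_SP: WQAssessment
    assessment_FP: WQAssessment
    production: ProductionRecord
    breeding_farm_id: str = ""
    finishing_farm_id: str = ""
    rearing_farm_id: Optional[str] = None

    @classmethod
    def build(cls, system_id: str, labels_held: Iterable[str], **kwargs):
        """Construct with ``assigned_label`` derived from ``labels_held``."""
        held = frozenset(labels_held)
        return cls(
            system_id=system_id,
            labels_held=held,
            assigned_label=assign_label_type(held),
            **kwargs,
        )


def validate_system(system: BreedToFinishSystem) -> list[str]:
    """Collect invariant violations for one system (empty list = valid).

    Violations are returned, not raised, so callers can report them all at
    once.  Cross-system invariants (unique finishing farms) are checked by
    :func:`validate_population`.
    """
    violations: list[str] = []
    try:
        expected = assign_label_type(system.labels_held)
    except VocabularyError as exc:
        violations.append(f"labels_held: {exc}")
    else:
        if system.assigned_label is not expected:
            violations.append(
                f"assigned_label: {system.assigned_label.label!r} is not the "
                f"most demanding label held (expected {expected.label!r})"
            )
    for stage, assessment in (
        ("assessment_SP", system.assessment_SP),
        ("assessment_FP", system.assessment_FP),
    ):
        for name, score in zip(
            ("p_health", "p_feeding", "p_behaviour", "p_housing"),
            assessment.scores,
        ):
            if not (0.0 <= score <= 100.0):
                violations.append(
                    f"{stage}.{name}: score {score!r} outside [0, 100]"
                )
    for issue in system.production.validate():
        violations.append(f"production.{issue}")
    if not system.finishing_farm_id:
        violations.append("finishing_farm_id: must be set")
    return violations


def validate_population(systems: Iterable[BreedToFinishSystem]) -> list[str]:
    """Per-system violations plus the unique-finishing-farm invariant."""
    systems = list(systems)
    violations: list[str] = []
    for system in systems:
        violations.extend(
            f"{system.system_id}: {v}" for v in validate_system(system)
        )
    seen: dict[str, str] = {}
    for system in systems:
        fid = system.finishing_farm_id
        if fid and fid in seen:
            violations.append(
                f"{system.system_id}: finishing_farm_id {fid!r} already used "
                f"by {seen[fid]}"
            )
        seen.setdefault(fid, system.system_id)
    return violations
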