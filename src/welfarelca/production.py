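"""Life-year accounting per kg deadweight.

Converts annualized production records into the quantities the welfare
metrics need: life-years per kg deadweight (DW) for each production stage
(``y_SP``, ``y_FP``) and the corresponding stage proportions (``t_SP``,
``t_FP``).  Cull-sow deadweight is folded into a single effective-DW
denominator by economic allocation, with fattening-pig DW as numeraire.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from welfarelca.errors import AllocationError, DegenerateRecordError

DAYS_PER_YEAR = 365.0


class MortalityAssumption(str, Enum):
    """How fattening pigs that died on farm are credited life-time.

    ``AVERAGE_SLAUGHTER_AGE`` (default): all weaned pigs — including those
    that later died or were culled on farm — are assumed to live the mean
    age of the pigs that went to slaughter.  ``DEATH_AT_WEANING`` credits
    fattening life-time only to pigs that reached slaughter (lower bound,
    used for sensitivity checks).
    """

    AVERAGE_SLAUGHTER_AGE = "average_slaughter_age"
    DEATH_AT_WEANING = "death_at_weaning"


@dataclass(frozen=True)
class ProductionRecord:
    """Annualized herd, throughput, weight and price data for one system."""

    sows_avg: float  # average breeding sows on farm over the year
    born_alive_per_year: float  # piglets born alive / yr
    weaned_per_year: float  # piglets weaned / yr
    weaning_age: float  # days
    slaughtered_per_year: float  # fattening pigs sent to slaughter / yr
    slaughter_age: float  # mean age at slaughter, days
    deadweight_per_pig: float  # kg DW per fattening pig
    cull_sows_per_year: float  # culled sows / yr
    cull_sow_deadweight: float  # kg DW per cull sow
    price_fattening: float  # currency per kg fattening DW
    price_cull: float  # currency per kg cull-sow DW

    def validate(self) -> list[str]:
        """Return human-readable invariant violations (empty = valid)."""
        violations: list[str] = []
        for name in (
            "sows_avg",
            "born_alive_per_year",
            "weaned_per_year",
            "weaning_age",
            "slaughtered_per_year",
            "slaughter_age",
            "deadweight_per_pig",
            "cull_sows_per_year",
            "cull_sow_deadweight",
            "price_fattening",
            "price_cull",
        ):
            if getattr(self, name) < 0:
                violations.append(f"{name}: must be >= 0, got {getattr(self, name)!r}")
        if self.weaned_per_year > self.born_alive_per_year:
            violations.append(
                "weaned_per_year: exceeds born_alive_per_year "
                f"({self.weaned_per_year!r} > {self.born_alive_per_year!r})"
            )
        if self.slaughtered_per_year > self.weaned_per_year:
            violations.append(
                "slaughtered_per_year: exceeds weaned_per_year "
                f"({self.slaughtered_per_year!r} > {self.weaned_per_year!r})"
            )
        if self.weaning_age >= self.slaughter_age:
            violations.append(
                "weaning_age: must be < slaughter_age "
                f"({self.weaning_age!r} >= {self.slaughter_age!r})"
            )
        return violations


@dataclass(frozen=True)
class LifeYearsProfile:
    """Life-years per kg DW by stage and the derived stage proportions."""

    y_SP: float
    y_FP: float
    t_SP: float
    t_FP: float

    def __post_init__(self) -> None:
        if self.y_SP < 0 or self.y_FP < 0:
            raise ValueError("life-years per kg must be non-negative")
        if abs(self.t_SP + self.t_FP - 1.0) > 1e-9:
            raise ValueError(
                f"stage proportions must sum to 1, got {self.t_SP + self.t_FP!r}"
            )

    @property
    def y_total(self) -> float:
        """Total life-years per kg DW across both stages."""
        return self.y_SP + self.y_FP


def effective_deadweight(record: ProductionRecord) -> float:
    """Annual deadweight output in fattening-pig-equivalent kg.

    Cull-sow DW is a co-product; it is converted onto the fattening-pig
    scale by economic allocation, i.e. scaled by the price ratio
    ``price_cull / price_fattening`` before being added to the fattening
    DW output.

    Raises
    ------
    AllocationError
        If the reference (fattening) price is not positive.
    DegenerateRecordError
        If the record produces no deadweight at all.
    """
    if record.price_fattening <= 0:
        raise AllocationError(
            f"price_fattening must be > 0 for economic allocation, "
            f"got {record.price_fattening!r}"
        )
    dw_fat = record.slaughtered_per_year * record.deadweight_per_pig
    dw_cull = record.cull_sows_per_year * record.cull_sow_deadweight
    total = dw_fat + dw_cull * (record.price_cull / record.price_fattening)
    if total <= 0:
        raise DegenerateRecordError("record produces zero effective deadweight")
    return total


def life_years_per_kg(
    record: ProductionRecord,
    assumption: MortalityAssumption = MortalityAssumption.AVERAGE_SLAUGHTER_AGE,
) -> LifeYearsProfile:
    """Life-years needed per kg DW, by production stage.

    Sows-and-piglets stage: each sow on farm contributes her full year;
    each piglet born alive is credited its pre-weaning life
    (``weaning_age`` days — all born-alive piglets are credited this,
    paralleling the fattening-stage mortality assumption).

    Fattening stage: under the default assumption every weaned pig lives
    from weaning to the mean slaughter age; under ``DEATH_AT_WEANING``
    only slaughtered pigs do.

    Both totals are divided by the effective (allocation-adjusted) annual
    deadweight output, giving intensive quantities that are invariant to
    uniform scaling of the herd.
    """
    violations = record.validate()
    if violations:
        raise ValueError("invalid production record: " + "; ".join(violations))
    eff_dw = effective_deadweight(record)

    sp_life_years = (
        record.sows_avg
        + record.born_alive_per_year * record.weaning_age / DAYS_PER_YEAR
    )
    fattening_days = record.slaughter_age - record.weaning_age
    if assumption is MortalityAssumption.AVERAGE_SLAUGHTER_AGE:
        fp_head = record.weaned_per_year
    elif assumption is MortalityAssumption.DEATH_AT_WEANING:
        fp_head = record.slaughtered_per_year
    else:  # pragma: no cover - closed vocabulary
        raise ValueError(f"unknown mortality assumption {assumption!r}")
    fp_life_years = fp_head * fattening_days / DAYS_PER_YEAR

    y_sp = sp_life_years / eff_dw
    y_fp = fp_life_years / eff_dw
    t_sp, t_fp = stage_proportions(y_sp, y_fp)
    return LifeYearsProfile(y_SP=y_sp, y_FP=y_fp, t_SP=t_sp, t_FP=t_fp)


def stage_proportions(y_SP: float, y_FP: float) -> tuple[float, float]:
    """Proportion of life-years contributed by each stage (sums to one)."""
    if y_SP < 0 or y_FP < 0:
        raise ValueError("life-years per kg must be non-negative")
    total = y_SP + y_FP
    if total <= 0:
        raise DegenerateRecordError(
            "cannot form stage proportions: total life-years is zero"
        )
    return y_SP / total, y_FP / total
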