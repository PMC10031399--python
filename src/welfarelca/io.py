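"""Tabular serialization and the end-to-end pipeline.

Systems travel as plain CSV with a versioned ``# schema=`` header line;
analysis results are bundled as a set of CSV tables plus a JSON metadata
block carrying the seed, config digest and package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

import welfarelca
from welfarelca.aggregation import (
    PrincipleWeighting,
    WEIGHTING_PRESETS,
    WQAssessment,
    overall_wq_score,
)
from welfarelca.domain import (
    BreedToFinishSystem,
    HusbandryType,
    LabelType,
    validate_population,
)
from welfarelca.errors import ConfigurationError, WelfareLCAError
from welfarelca.metrics import MetricSpec, canonical_grid, metric_grid
from welfarelca.production import ProductionRecord, life_years_per_kg
from welfarelca.stats import (
    DEFAULT_ALPHA,
    GroupedSample,
    compact_letters,
    dunn_posthoc,
    grouped_sample_from_systems,
    independent_subset,
    kruskal_wallis,
    rank_correlation_matrix,
)

logger = logging.getLogger("welfarelca")

SYSTEMS_SCHEMA = "welfarelca.systems.v1"

_PRODUCTION_FIELDS = (
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
)

SYSTEMS_COLUMNS = (
    "system_id",
    "labels_held",
    "assigned_label",
    "breeding_husbandry",
    "finishing_husbandry",
    "sp_p_health",
    "sp_p_feeding",
    "sp_p_behaviour",
    "sp_p_housing",
    "fp_p_health",
    "fp_p_feeding",
    "fp_p_behaviour",
    "fp_p_housing",
    *_PRODUCTION_FIELDS,
    "breeding_farm_id",
    "rearing_farm_id",
    "finishing_farm_id",
)

_LABEL_ALIASES = {
    "qms": "red_tractor",
    "quality_meat_scotland": "red_tractor",
    "red tractor": "red_tractor",
    "rspca": "rspca_assured",
    "rspca assured": "rspca_assured",
    "free range": "free_range",
    "": "none",
}


def normalize_label(name: str) -> str:
    """Map free-text label names onto the closed vocabulary."""
    cleaned = name.strip().lower().replace("-", " ")
    cleaned = _LABEL_ALIASES.get(cleaned, cleaned).replace(" ", "_")
    return _LABEL_ALIASES.get(cleaned, cleaned)


def systems_to_frame(systems: Iterable[BreedToFinishSystem]) -> pd.DataFrame:
    rows = []
    for s in systems:
        row = {
            "system_id": s.system_id,
            "labels_held": ";".join(sorted(s.labels_held)),
            "assigned_label": s.assigned_label.label,
            "breeding_husbandry": s.husbandry.breeding,
            "finishing_husbandry": s.husbandry.finishing,
        }
        for prefix, assessment in (("sp", s.assessment_SP), ("fp", s.assessment_FP)):
            row[f"{prefix}_p_health"] = assessment.p_health
            row[f"{prefix}_p_feeding"] = assessment.p_feeding
            row[f"{prefix}_p_behaviour"] = assessment.p_behaviour
            row[f"{prefix}_p_housing"] = assessment.p_housing
        for name in _PRODUCTION_FIELDS:
            row[name] = getattr(s.production, name)
        row["breeding_farm_id"] = s.breeding_farm_id
        row["rearing_farm_id"] = s.rearing_farm_id or ""
        row["finishing_farm_id"] = s.finishing_farm_id
        rows.append(row)
    return pd.DataFrame(rows, columns=SYSTEMS_COLUMNS)


def write_systems(systems: Iterable[BreedToFinishSystem], path: str | Path) -> None:
    """Write a systems table as versioned CSV (UTF-8, '.' decimals)."""
    path = Path(path)
    frame = systems_to_frame(systems)
    with open(path, "w", encoding="utf-8", newline="") as handle:
        handle.write(f"# schema={SYSTEMS_SCHEMA}\n")
        frame.to_csv(handle, index=False, float_format="%.12g")


def read_systems(path: str | Path) -> list[BreedToFinishSystem]:
    """Read and validate a systems CSV written by :func:`write_systems`."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as handle:
        first = handle.readline().strip()
    if first != f"# schema={SYSTEMS_SCHEMA}":
        raise WelfareLCAError(
            f"{path}: unrecognized header {first!r}; expected "
            f"'# schema={SYSTEMS_SCHEMA}'"
        )
    frame = pd.read_csv(path, comment="#", dtype={"system_id": str}, keep_default_na=False)
    missing = set(SYSTEMS_COLUMNS) - set(frame.columns)
    if missing:
        raise WelfareLCAError(f"{path}: missing column(s) {sorted(missing)}")

    systems: list[BreedToFinishSystem] = []
    for i, row in frame.iterrows():
        rownum = i + 3  # header comment + column row + 1-based
        try:
            labels_held = frozenset(
                normalize_label(part)
                for part in str(row["labels_held"]).split(";")
                if part.strip()
            )
            production = ProductionRecord(
                **{name: float(row[name]) for name in _PRODUCTION_FIELDS}
            )
            system = BreedToFinishSystem(
                system_id=str(row["system_id"]),
                labels_held=labels_held,
                assigned_label=LabelType.from_name(
                    normalize_label(str(row["assigned_label"]))
                ),
                husbandry=HusbandryType(
                    breeding=str(row["breeding_husbandry"]),
                    finishing=str(row["finishing_husbandry"]),
                ),
                assessment_SP=WQAssessment(
                    float(row["sp_p_health"]),
                    float(row["sp_p_feeding"]),
                    float(row["sp_p_behaviour"]),
                    float(row["sp_p_housing"]),
                ),
                assessment_FP=WQAssessment(
                    float(row["fp_p_health"]),
                    float(row["fp_p_feeding"]),
                    float(row["fp_p_behaviour"]),
                    float(row["fp_p_housing"]),
                ),
                production=production,
                breeding_farm_id=str(row["breeding_farm_id"]),
                rearing_farm_id=str(row["rearing_farm_id"]) or None,
                finishing_farm_id=str(row["finishing_farm_id"]),
            )
        except (WelfareLCAError, ValueError) as exc:
            raise WelfareLCAError(f"{path}: row {rownum}: {exc}") from exc
        systems.append(system)
    issues = validate_population(systems)
    if issues:
        raise WelfareLCAError(
            f"{path}: validation failed: " + "; ".join(issues[:10])
        )
    return systems


@dataclass(frozen=True)
class AnalysisConfig:
    alpha: float = DEFAULT_ALPHA
    seed: int | None = None
    wq_weighting: str = "standard"
    metric_ids: tuple[str, ...] | None = None  # None = full canonical grid
    use_subset: bool = True  # statistics on the independent subset


@dataclass
class ResultsBundle:
    """All pipeline outputs plus run metadata."""

    overall_wq: pd.DataFrame  # system_id, label, husbandry, y columns, wq score
    costs: pd.DataFrame  # tidy metric grid
    omnibus: pd.DataFrame  # KW results per (variable, grouping)
    pairwise: pd.DataFrame  # Dunn/Holm comparisons
    letters: pd.DataFrame  # compact letter displays
    rank_corr_r: pd.DataFrame
    rank_corr_p: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def _config_digest(config: AnalysisConfig) -> str:
    return hashlib.sha256(repr(config).encode()).hexdigest()[:16]


def _select_specs(metric_ids: Sequence[str] | None) -> list[MetricSpec]:
    grid = canonical_grid()
    if metric_ids is None:
        return grid
    by_id = {spec.metric_id: spec for spec in grid}
    unknown = [m for m in metric_ids if m not in by_id]
    if unknown:
        raise ConfigurationError(
            f"unknown metric id(s) {unknown}; valid ids: {sorted(by_id)}"
        )
    return [by_id[m] for m in metric_ids]


def run_pipeline(
    systems: Sequence[BreedToFinishSystem],
    config: AnalysisConfig | None = None,
) -> ResultsBundle:
    """Execute the full analysis on a list of systems.

    Life-year accounting -> overall WQ scores -> metric grid ->
    independent-subset selection -> omnibus/post hoc statistics and the
    rank-correlation matrix.  Metric tables cover all systems; statistics
    are computed on the independent subset (one system per shared-farm
    cluster) unless ``use_subset`` is off.
    """
    if config is None:
        config = AnalysisConfig()
    if len(systems) < 2:
        raise WelfareLCAError("pipeline requires at least two systems")
    weighting: PrincipleWeighting = WEIGHTING_PRESETS[config.wq_weighting]
    logger.info(
        "pipeline start: %d systems, config digest %s",
        len(systems),
        _config_digest(config),
    )

    # Stage 1-2: life-year accounting and overall WQ scores.
    try:
        wq_rows = []
        for s in systems:
            profile = life_years_per_kg(s.production)
            wq_rows.append(
                {
                    "system_id": s.system_id,
                    "label": s.assigned_label.label,
                    "breeding_husbandry": s.husbandry.breeding,
                    "finishing_husbandry": s.husbandry.finishing,
                    "y_SP": profile.y_SP,
                    "y_FP": profile.y_FP,
                    "y_total": profile.y_total,
                    "t_SP": profile.t_SP,
                    "overall_wq": overall_wq_score(
                        s.assessment_SP,
                        s.assessment_FP,
                        weighting,
                        profile.t_SP,
                        profile.t_FP,
                    ),
                }
            )
        overall = pd.DataFrame(wq_rows).sort_values("system_id").reset_index(drop=True)
    except WelfareLCAError as exc:
        raise WelfareLCAError(f"wq_aggregation stage: {exc}") from exc

    # Stage 3: metric grid over every system.
    try:
        specs = _select_specs(config.metric_ids)
        costs = metric_grid(systems, specs)
    except WelfareLCAError as exc:
        raise WelfareLCAError(f"metric_family stage: {exc}") from exc
    logger.info("metric grid: %d rows (%d variants)", len(costs), len(specs))

    # Stage 4: independent subset for statistics.
    if config.use_subset:
        subset = independent_subset(systems, seed=config.seed)
    else:
        subset = list(systems)
    subset_ids = {s.system_id for s in subset}
    logger.info("statistics subset: %d of %d systems", len(subset), len(systems))

    # Stage 5: omnibus + post hoc statistics per variable and grouping.
    groupings = {
        "label": lambda s: s.assigned_label.label,
        "breeding_husbandry": lambda s: s.husbandry.breeding,
        "finishing_husbandry": lambda s: s.husbandry.finishing,
    }
    wq_by_id = dict(zip(overall["system_id"], overall["overall_wq"]))
    variables: dict[str, dict[str, float]] = {
        "overall_wq": wq_by_id,
        "y_SP": dict(zip(overall["system_id"], overall["y_SP"])),
        "y_FP": dict(zip(overall["system_id"], overall["y_FP"])),
    }
    for metric_id, frame in costs.groupby("metric_id"):
        variables[f"cost:{metric_id}"] = dict(
            zip(frame["system_id"], frame["cost"])
        )

    omnibus_rows, pairwise_rows, letter_rows = [], [], []
    for var_name, values in variables.items():
        for group_name, group_of in groupings.items():
            try:
                sample = _grouped(subset, values, group_of)
            except WelfareLCAError:
                continue
            if len(sample.groups) < 2:
                logger.info(
                    "skipping omnibus for %s by %s: fewer than two groups",
                    var_name,
                    group_name,
                )
                continue
            kw = kruskal_wallis(sample)
            omnibus_rows.append(
                {
                    "variable": var_name,
                    "grouping": group_name,
                    "H": kw.H,
                    "df": kw.df,
                    "p_value": kw.p_value,
                }
            )
            comparisons = dunn_posthoc(sample, alpha=config.alpha)
            for c in comparisons:
                pairwise_rows.append(
                    {
                        "variable": var_name,
                        "grouping": group_name,
                        "group_a": c.group_a,
                        "group_b": c.group_b,
                        "z": c.z_statistic,
                        "p_raw": c.p_raw,
                        "p_adjusted": c.p_adjusted,
                        "significant": c.significant,
                    }
                )
            letters = compact_letters(comparisons, sample.groups)
            for group, letter in letters.items():
                letter_rows.append(
                    {
                        "variable": var_name,
                        "grouping": group_name,
                        "group": group,
                        "letters": letter,
                    }
                )

    # Stage 6: rank-correlation matrix across metric variants (+ overall WQ),
    # on the statistics subset.
    subset_costs = costs[costs["system_id"].isin(subset_ids)]
    rank_r, rank_p = rank_correlation_matrix(
        subset_costs, {k: v for k, v in wq_by_id.items() if k in subset_ids}
    )

    metadata = {
        "package_version": welfarelca.__version__,
        "n_systems": len(systems),
        "n_subset": len(subset),
        "alpha": config.alpha,
        "seed": config.seed,
        "wq_weighting": config.wq_weighting,
        "metric_ids": [spec.metric_id for spec in specs],
        "config_digest": _config_digest(config),
        "subset_system_ids": sorted(subset_ids),
    }
    return ResultsBundle(
        overall_wq=overall,
        costs=costs,
        omnibus=pd.DataFrame(
            omnibus_rows, columns=["variable", "grouping", "H", "df", "p_value"]
        ),
        pairwise=pd.DataFrame(
            pairwise_rows,
            columns=[
                "variable",
                "grouping",
                "group_a",
                "group_b",
                "z",
                "p_raw",
                "p_adjusted",
                "significant",
            ],
        ),
        letters=pd.DataFrame(
            letter_rows, columns=["variable", "grouping", "group", "letters"]
        ),
        rank_corr_r=rank_r,
        rank_corr_p=rank_p,
        metadata=metadata,
    )


def _grouped(systems, values, group_of) -> GroupedSample:
    return grouped_sample_from_systems(systems, values, group_of)


def write_bundle(bundle: ResultsBundle, out_dir: str | Path) -> None:
    """Serialize a results bundle as CSV tables plus metadata.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.overall_wq.to_csv(out / "overall_wq.csv", index=False, float_format="%.12g")
    bundle.costs.to_csv(out / "costs.csv", index=False, float_format="%.12g")
    bundle.omnibus.to_csv(out / "omnibus.csv", index=False, float_format="%.12g")
    bundle.pairwise.to_csv(out / "pairwise.csv", index=False, float_format="%.12g")
    bundle.letters.to_csv(out / "letters.csv", index=False)
    bundle.rank_corr_r.to_csv(out / "rank_correlation_r.csv", float_format="%.12g")
    bundle.rank_corr_p.to_csv(out / "rank_correlation_p.csv", float_format="%.12g")
    with open(out / "metadata.json", "w", encoding="utf-8") as handle:
        json.dump(bundle.metadata, handle, indent=2, sort_keys=True)
        handle.write("\n")


def render_report(bundle: ResultsBundle) -> str:
    """Plain-text summary: group medians, letters and adjusted p-values."""
    lines = ["welfarelca analysis report", "=" * 60]
    meta = bundle.metadata
    lines.append(
        f"systems: {meta.get('n_systems')} (statistics on "
        f"{meta.get('n_subset')} independent systems), "
        f"alpha={meta.get('alpha')}, seed={meta.get('seed')}"
    )
    lines.append(f"config digest: {meta.get('config_digest')}")
    lines.append("")
    for _, row in bundle.omnibus.iterrows():
        lines.append(
            f"{row['variable']} by {row['grouping']}: "
            f"H={row['H']:.3f}, df={int(row['df'])}, p={row['p_value']:.4g}"
        )
        sub = bundle.letters[
            (bundle.letters["variable"] == row["variable"])
            & (bundle.letters["grouping"] == row["grouping"])
        ]
        for _, lrow in sub.iterrows():
            lines.append(f"    {lrow['group']}: {lrow['letters']}")
    lines.append("")
    lines.append("pairwise comparisons (Holm-adjusted p < alpha marked *):")
    for _, row in bundle.pairwise.iterrows():
        flag = "*" if row["significant"] else " "
        lines.append(
            f"  {flag} {row['variable']} by {row['grouping']}: "
            f"{row['group_a']} vs {row['group_b']}: z={row['z']:.3f}, "
            f"p_adj={row['p_adjusted']:.4g}"
        )
    return "\n".join(lines) + "\n"
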