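"""Deterministic (point-estimate) cadmium exposure arithmetic.

Per-food daily exposure is evaluated at four summary levels:

* ``mean``         — mean concentration x mean intake
* ``median``       — median concentration x median intake
* ``p90``          — mean concentration x P90 intake
* ``extreme_p90``  — P90 concentration x P90 intake

With concentration in mg/kg (= ug/g) and intake in g/day the product is in
ug/day.  Dietary exposure is the sum over foods; total exposure adds a water
term (half-LOD concentration x daily volume) and a smoking term (tobacco Cd
per gram x grams per cigarette x cigarettes per day).  Risk is characterized
as the percentage of the provisional tolerable daily intake (PTDI).

Note the median level multiplies *median* concentration by median intake:
that is the convention the study's published per-food median exposures
follow.  The alternative (mean concentration x median intake) is available
via ``median_uses_mean_conc=True``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .tables import (
    ExposureConfig,
    FoodRecord,
    ValidationError,
    load_extreme_overrides,
    load_nondietary_levels,
)

__all__ = [
    "LEVELS",
    "ExposureBreakdown",
    "food_exposure_mean",
    "food_exposure_median",
    "food_exposure_p90",
    "food_exposure_extreme",
    "food_exposure",
    "dietary_total",
    "contribution_rates",
    "water_exposure",
    "tobacco_exposure",
    "total_exposure",
    "ptdi_fraction",
    "compute_breakdown",
]

logger = logging.getLogger(__name__)

LEVELS = ("mean", "median", "p90", "extreme_p90")

# one-sided 90% standard-normal quantile, for the P90-concentration fallback
_Z90 = 1.2816


def _check_nonnegative(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if value < 0:
            raise ValidationError(f"{name} must be >= 0, got {value}")


def food_exposure_mean(conc_mean: float, intake_mean: float) -> float:
    """Mean daily exposure from one food, ug/day."""
    _check_nonnegative(conc_mean=conc_mean, intake_mean=intake_mean)
    return conc_mean * intake_mean


def food_exposure_median(conc_median: float, intake_median: float) -> float:
    """Median-level daily exposure: median concentration x median intake."""
    _check_nonnegative(conc_median=conc_median, intake_median=intake_median)
    return conc_median * intake_median


def food_exposure_p90(conc_mean: float, intake_p90: float) -> float:
    """Upper (P90) daily exposure: mean concentration x P90 intake."""
    _check_nonnegative(conc_mean=conc_mean, intake_p90=intake_p90)
    return conc_mean * intake_p90


def food_exposure_extreme(
    conc_p90: float | None,
    intake_p90: float,
    override: float | None = None,
    *,
    conc_mean: float | None = None,
    conc_std: float | None = None,
    food_name: str = "?",
) -> float:
    """Extreme (P90 x P90) daily exposure, ug/day.

    When the P90 concentration is absent, a per-food ``override`` exposure is
    used if supplied; failing that, the concentration falls back to the
    normal-quantile approximation ``conc_mean + 1.2816 * conc_std`` with a
    logged warning.
    """
    _check_nonnegative(intake_p90=intake_p90)
    if conc_p90 is not None:
        _check_nonnegative(conc_p90=conc_p90)
        return conc_p90 * intake_p90
    if override is not None:
        _check_nonnegative(override=override)
        return override
    if conc_mean is None or conc_std is None:
        raise ValidationError(
            f"food {food_name!r}: extreme-P90 exposure unresolvable "
            "(no P90 concentration, no override, no mean/std fallback)"
        )
    logger.warning(
        "food %r: P90 concentration absent; using normal-quantile fallback "
        "mean + %.4f * std",
        food_name,
        _Z90,
    )
    return (conc_mean + _Z90 * conc_std) * intake_p90


def food_exposure(
    record: FoodRecord,
    level: str,
    extreme_overrides: dict[str, float] | None = None,
    *,
    median_uses_mean_conc: bool = False,
) -> float:
    """Daily exposure (ug/day) of one food at a summary level."""
    if level == "mean":
        return food_exposure_mean(record.conc_mean, record.intake_mean)
    if level == "median":
        conc = record.conc_mean if median_uses_mean_conc else record.conc_median
        return food_exposure_median(conc, record.intake_median)
    if level == "p90":
        return food_exposure_p90(record.conc_mean, record.intake_p90)
    if level == "extreme_p90":
        override = (extreme_overrides or {}).get(record.food_name)
        return food_exposure_extreme(
            record.conc_p90,
            record.intake_p90,
            override,
            conc_mean=record.conc_mean,
            conc_std=record.conc_std,
            food_name=record.food_name,
        )
    raise ValidationError(f"unknown exposure level {level!r}; expected one of {LEVELS}")


def dietary_total(
    records: list[FoodRecord],
    level: str,
    extreme_overrides: dict[str, float] | None = None,
    **kwargs,
) -> float:
    """Total dietary exposure: sum of per-food exposures at ``level``."""
    if not records:
        raise ValidationError("dietary_total requires at least one food record")
    return sum(food_exposure(r, level, extreme_overrides, **kwargs) for r in records)


def contribution_rates(per_food: list[float], total: float) -> list[float]:
    """Each food's percentage share of the dietary total."""
    if total <= 0:
        raise ValidationError("contribution rates undefined for total <= 0")
    return [100.0 * e / total for e in per_food]


def water_exposure(water_conc: float, water_volume: float) -> float:
    """Daily water cadmium dose: concentration (ug/L) x volume (L/day)."""
    _check_nonnegative(water_conc=water_conc, water_volume=water_volume)
    return water_conc * water_volume


def tobacco_exposure(
    tobacco_conc: float, cigarette_mass: float, cigarettes_per_day: float
) -> float:
    """Daily inhaled cadmium dose from smoking, ug/day.

    tobacco_conc is ug Cd per g tobacco, cigarette_mass g per cigarette.
    """
    _check_nonnegative(
        tobacco_conc=tobacco_conc,
        cigarette_mass=cigarette_mass,
        cigarettes_per_day=cigarettes_per_day,
    )
    return tobacco_conc * cigarette_mass * cigarettes_per_day


def total_exposure(dietary: float, water: float, smoking: float) -> float:
    """Total daily environmental cadmium exposure, ug/day."""
    _check_nonnegative(dietary=dietary, water=water, smoking=smoking)
    return dietary + water + smoking


def ptdi_fraction(exposure: float, ptdi: float) -> float:
    """Exposure as a percentage of the provisional tolerable daily intake."""
    if ptdi <= 0:
        raise ValidationError("ptdi must be positive")
    _check_nonnegative(exposure=exposure)
    return 100.0 * exposure / ptdi


@dataclass
class ExposureBreakdown:
    """Per-source exposure table at all four summary levels.

    ``per_food`` is indexed by food name with columns
    ``exposure_<level>`` (ug/day) and ``contribution_<level>`` (percent);
    ``totals`` maps level -> {dietary, water, smoking, total} in ug/day;
    ``ptdi_fractions`` maps level -> total exposure as % of the PTDI.
    """

    per_food: pd.DataFrame
    totals: dict[str, dict[str, float]]
    ptdi_fractions: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Flat table: foods, then dietary/water/smoking/total rows."""
        extra_rows = {}
        for source in ("dietary", "water", "smoking", "total"):
            extra_rows[source] = {
                f"exposure_{lv}": self.totals[lv][source] for lv in LEVELS
            }
        extra = pd.DataFrame.from_dict(extra_rows, orient="index")
        return pd.concat([self.per_food, extra])


def compute_breakdown(
    records: list[FoodRecord],
    config: ExposureConfig,
    *,
    extreme_overrides: dict[str, float] | None = None,
    nondietary_levels: dict[str, dict[str, float]] | None = None,
    median_uses_mean_conc: bool = False,
) -> ExposureBreakdown:
    """Full point-estimate exposure breakdown (the published exposure-source
    table's shape: per-food rows plus dietary/water/smoking/total rows).

    Water exposure at the mean/median levels is concentration x volume from
    ``config``; the upper levels and all smoking levels are survey-derived
    scalars taken from ``nondietary_levels`` (bundled defaults when omitted,
    since they are not derivable from the summary food table).
    """
    if extreme_overrides is None:
        extreme_overrides = load_extreme_overrides()
    if nondietary_levels is None:
        nondietary_levels = load_nondietary_levels()

    water_mean = water_exposure(config.water_conc, config.water_volume)
    water_levels = {
        "mean": water_mean,
        "median": water_mean,
        "p90": nondietary_levels["water"]["p90"],
        "extreme_p90": nondietary_levels["water"]["extreme_p90"],
    }
    smoking_levels = {lv: nondietary_levels["smoking"][lv] for lv in LEVELS}

    per_food = pd.DataFrame(index=pd.Index([r.food_name for r in records], name="food"))
    totals: dict[str, dict[str, float]] = {}
    for lv in LEVELS:
        exposures = [
            food_exposure(
                r, lv, extreme_overrides, median_uses_mean_conc=median_uses_mean_conc
            )
            for r in records
        ]
        dietary = sum(exposures)
        per_food[f"exposure_{lv}"] = exposures
        per_food[f"contribution_{lv}"] = contribution_rates(exposures, dietary)
        total = total_exposure(dietary, water_levels[lv], smoking_levels[lv])
        totals[lv] = {
            "dietary": dietary,
            "water": water_levels[lv],
            "smoking": smoking_levels[lv],
            "total": total,
        }
    fractions = {lv: ptdi_fraction(totals[lv]["total"], config.ptdi) for lv in LEVELS}
    return ExposureBreakdown(per_food=per_food, totals=totals, ptdi_fractions=fractions)
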