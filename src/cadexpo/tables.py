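"""Data model and I/O for food summary tables, configuration and cohorts.

The central input is a per-food summary table: for each aggregated food
category, the mean/std/median/P90 of its cadmium concentration (mg/kg) and
of its daily consumption (g/day).  The bundled default table describes the
14 food categories surveyed among Shanghai adults over 40; an optional
reference column carries the mean concentration from a year-2000 national
survey (never used computationally).

Missing cells (e.g. the tuber P90 concentration) are represented as ``None``,
never as zero — imputing zero would silently corrupt upper-bound exposure
totals.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

__all__ = [
    "FoodRecord",
    "ExposureConfig",
    "ValidationError",
    "read_food_table",
    "write_food_table",
    "load_default_food_table",
    "load_nondietary_levels",
    "load_extreme_overrides",
    "load_output_distribution_table",
    "read_config",
    "write_config",
    "read_cohort_table",
    "write_cohort_table",
    "derive_ptdi",
]


class ValidationError(ValueError):
    """Raised when an input table or configuration violates its contract."""


# column order of the delimited food table; "food" is the key column
_FOOD_COLUMNS = (
    "conc_mean",
    "conc_std",
    "conc_median",
    "conc_p90",
    "conc_ref2000",
    "intake_mean",
    "intake_std",
    "intake_median",
    "intake_p90",
)
_REQUIRED_FOOD_COLUMNS = (
    "conc_mean",
    "conc_std",
    "conc_median",
    "intake_mean",
    "intake_std",
    "intake_median",
    "intake_p90",
)


@dataclass(frozen=True)
class FoodRecord:
    """Summary statistics for one food category.

    Concentrations are in mg/kg (equivalently ug/g); intakes in g/day.
    Optional statistics are ``None`` when the source table leaves the cell
    blank.  ``conc_ref2000`` is a historical reference value carried through
    but never used in any computation.
    """

    food_name: str
    conc_mean: float
    conc_std: float
    conc_median: float
    intake_mean: float
    intake_std: float
    intake_median: float
    intake_p90: float
    conc_p90: float | None = None
    conc_ref2000: float | None = None

    def __post_init__(self) -> None:
        for field in dataclasses.fields(self):
            if field.name == "food_name":
                continue
            value = getattr(self, field.name)
            if value is not None and value < 0:
                raise ValidationError(
                    f"food {self.food_name!r}: {field.name} must be >= 0, got {value}"
                )
        if self.conc_p90 is not None and self.conc_median > self.conc_p90:
            raise ValidationError(
                f"food {self.food_name!r}: conc_median > conc_p90"
            )
        if self.intake_median > self.intake_p90:
            raise ValidationError(
                f"food {self.food_name!r}: intake_median > intake_p90"
            )


@dataclass
class ExposureConfig:
    """Scalar constants of the exposure assessment.

    Defaults reproduce the study setting: a provisional tolerable monthly
    intake (PTMI) of 25 ug/kg-bw/month for a 60 kg adult, converted to a
    provisional tolerable daily intake (PTDI) of 49.5 ug/day; tobacco at
    1.5 ug Cd per cigarette-gram; tap water at half the 0.05 ug/L detection
    limit with 1.2 L drunk per day.
    """

    ptmi: float = 25.0  # ug/kg-bw/month
    body_weight: float = 60.0  # kg
    ptdi: float = 49.5  # ug/day
    tobacco_conc: float = 1.5  # ug Cd per g tobacco
    cigarette_mass: float = 1.0  # g tobacco per cigarette
    water_conc: float = 0.025  # ug/L (half-LOD substitution)
    water_volume: float = 1.2  # L/day
    lod: float = 0.05  # ug/L
    n_iterations: int = 100_000
    seed: int = 42
    smoking_prevalence: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"total": 0.295, "male": 0.662, "female": 0.033}
    )

    def __post_init__(self) -> None:
        for name in (
            "ptmi",
            "body_weight",
            "ptdi",
            "tobacco_conc",
            "cigarette_mass",
            "water_conc",
            "water_volume",
            "lod",
            "n_iterations",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"config field {name} must be positive")
        for key, p in self.smoking_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"smoking prevalence {key}={p} outside [0, 1]")

    @property
    def water_exposure(self) -> float:
        """Mean daily water cadmium dose, ug/day."""
        return self.water_conc * self.water_volume


def derive_ptdi(ptmi: float, body_weight: float, days_per_month: float) -> float:
    """Convert a monthly tolerable intake to a daily one.

    ``ptmi`` is in ug per kg body weight per month; the result is ug/day.
    The study's printed PTDI of 49.5 ug/day corresponds to 25 x 60 / 30.3.
    """
    if ptmi <= 0 or body_weight <= 0 or days_per_month <= 0:
        raise ValidationError("derive_ptdi arguments must all be positive")
    return ptmi * body_weight / days_per_month


def _sniff_sep(path: Path) -> str:
    header = path.open("r", encoding="utf-8").readline()
    return "\t" if "\t" in header else ","


def read_food_table(path: str | Path) -> list[FoodRecord]:
    """Read a delimited (comma or tab) per-food summary table.

    One header row naming the statistics is required; empty cells become
    absent (``None``) statistics.  Raises :class:`ValidationError` naming the
    offending row and column for malformed headers, negative values or
    duplicate food names.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValidationError(f"{path}: empty food table")
    df = pd.read_csv(path, sep=_sniff_sep(path), comment="#")
    if "food" not in df.columns:
        raise ValidationError(f"{path}: header must contain a 'food' column")
    missing = [c for c in _REQUIRED_FOOD_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: header missing columns {missing}")
    dupes = df["food"][df["food"].duplicated()].tolist()
    if dupes:
        raise ValidationError(f"{path}: duplicate food name(s) {dupes}")

    records: list[FoodRecord] = []
    for idx, row in df.iterrows():
        kwargs: dict[str, float | None] = {}
        for col in _FOOD_COLUMNS:
            raw = row.get(col)
            if raw is None or pd.isna(raw):
                kwargs[col] = None
            else:
                value = float(raw)
                if value < 0:
                    raise ValidationError(
                        f"{path}: negative value in row {idx} ({row['food']!r}), "
                        f"column {col!r}"
                    )
                kwargs[col] = value
        for col in _REQUIRED_FOOD_COLUMNS:
            if kwargs[col] is None:
                raise ValidationError(
                    f"{path}: missing required cell in row {idx} "
                    f"({row['food']!r}), column {col!r}"
                )
        records.append(FoodRecord(food_name=str(row["food"]), **kwargs))
    return records


def write_food_table(records: Iterable[FoodRecord], path: str | Path) -> None:
    """Write records as CSV; ``repr`` float formatting makes re-reading exact."""
    rows = []
    for rec in records:
        row = {"food": rec.food_name}
        row.update({c: getattr(rec, c) for c in _FOOD_COLUMNS})
        rows.append(row)
    df = pd.DataFrame(rows, columns=("food",) + _FOOD_COLUMNS)
    df.to_csv(path, index=False)


def _data_path(name: str):
    return resources.files("cadexpo.data").joinpath(name)


def load_default_food_table() -> list[FoodRecord]:
    """The bundled 14-category Shanghai food summary table."""
    with resources.as_file(_data_path("food_table.csv")) as p:
        return read_food_table(p)


def load_nondietary_levels() -> dict[str, dict[str, float]]:
    """Bundled survey-derived water and smoking exposures per summary level."""
    payload = json.loads(_data_path("nondietary_levels.json").read_text())
    payload.pop("comment", None)
    return payload


def load_extreme_overrides() -> dict[str, float]:
    """Bundled extreme-P90 exposure overrides (ug/day) keyed by food name."""
    payload = json.loads(_data_path("extreme_overrides.json").read_text())
    payload.pop("comment", None)
    return {k: float(v) for k, v in payload.items()}


def load_output_distribution_table() -> pd.DataFrame:
    """Reported fitted output distributions (mean/median/std/P5/P95/range)
    of the probabilistic exposure models, one row per population stratum."""
    with resources.as_file(_data_path("output_distributions.csv")) as p:
        return pd.read_csv(p).set_index("model")


def read_config(path: str | Path | None = None) -> ExposureConfig:
    """Read an :class:`ExposureConfig` from YAML/JSON; ``None`` loads defaults."""
    if path is None:
        raw = yaml.safe_load(_data_path("config.yaml").read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValidationError("config file must contain a mapping")
    known = {f.name for f in dataclasses.fields(ExposureConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config field(s): {sorted(unknown)}")
    return ExposureConfig(**raw)


def write_config(config: ExposureConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(config), sort_keys=False))


# ---------------------------------------------------------------------------
# cohort tables

_COHORT_BASE_COLUMNS = ("id", "age", "sex", "smoker", "cigarettes_per_day")


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read an individual-level cohort table (one row per participant).

    Expected columns: id, age (years), sex ('male'/'female'), smoker (bool),
    cigarettes_per_day, per-food intake columns named ``intake_<food>``
    (g/day), and optionally ucd/bcd (ug/L).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), comment="#")
    missing = [c for c in _COHORT_BASE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: cohort table missing columns {missing}")
    df["smoker"] = df["smoker"].astype(bool)
    if (df["age"] <= 0).any():
        raise ValidationError(f"{path}: ages must be positive")
    bad_sex = set(df["sex"].unique()) - {"male", "female"}
    if bad_sex:
        raise ValidationError(f"{path}: unknown sex value(s) {sorted(bad_sex)}")
    if (df.loc[~df["smoker"], "cigarettes_per_day"] != 0).any():
        raise ValidationError(f"{path}: non-smokers must have cigarettes_per_day = 0")
    intake_cols = [c for c in df.columns if c.startswith("intake_")]
    if intake_cols and (df[intake_cols] < 0).any().any():
        raise ValidationError(f"{path}: intakes must be >= 0")
    return df


def write_cohort_table(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False)


def intake_columns(cohort: pd.DataFrame) -> list[str]:
    """Names of the per-food intake columns of a cohort table."""
    return [c for c in cohort.columns if c.startswith("intake_")]
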