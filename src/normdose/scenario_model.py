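"""Hypothetical usage scenarios: who uses each product, for how long, and
through which exposure pathways.

Each consumer-product category carries a body location, an average daily usage
time during normal use, an overuse time (normal + 2 h, modelling oversleeping,
accidental prolonged wear, etc.) and the set of exposure pathways through
which its radioactivity can reach the user.  Daily usage times convert to
annual exposure hours assuming use on every day of the year (configurable).

The packaged scenario table covers ten product categories.  One published
overuse time ("1 day 2 h" for clothing, i.e. 26 h/d) exceeds a physical day
and is clamped to 24 h/d with a load-time warning.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import DataQualityWarning, FormatError, ValidationError

DEFAULT_DAYS_PER_YEAR = 365

_DURATION_RE = re.compile(
    r"^\s*(?:(?P<days>\d+)\s*(?:d|day|days))?"
    r"\s*(?:(?P<hours>\d+(?:\.\d+)?)\s*h(?:r|rs|our|ours)?)?"
    r"\s*(?:(?P<minutes>\d+(?:\.\d+)?)\s*min(?:s|ute|utes)?)?\s*$",
    re.IGNORECASE,
)

VALID_PATHWAYS = frozenset({"external", "inhalation", "ingestion"})


def parse_duration(text: str | float) -> float:
    """Parse a usage time into decimal hours.

    Accepts ``"H h M min"``, ``"M min"``, ``"D day H h"`` and plain decimal
    hours.  Minutes convert at exactly 1/60 h.
    """
    if isinstance(text, (int, float)):
        return float(text)
    text = str(text).strip()
    try:
        return float(text)
    except ValueError:
        pass
    m = _DURATION_RE.match(text)
    if not m or not any(m.groupdict().values()):
        raise FormatError(f"cannot parse usage time {text!r}")
    days = float(m.group("days") or 0)
    hours = float(m.group("hours") or 0)
    minutes = float(m.group("minutes") or 0)
    return days * 24.0 + hours + minutes / 60.0


def format_duration(hours: float) -> str:
    """Format decimal hours as ``"H h M min"`` (whole minutes)."""
    if hours < 0:
        raise ValidationError("duration must be non-negative")
    total_min = round(hours * 60)
    h, m = divmod(total_min, 60)
    if h and m:
        return f"{h} h {m} min"
    if h:
        return f"{h} h"
    return f"{m} min"


@dataclass(frozen=True)
class UsageScenario:
    """One product category's usage assumptions and exposure pathways."""

    product_category: str
    eu_classification: str
    usage_location: str
    daily_use_normal: float  # h/d
    daily_use_overuse: float  # h/d
    pathways: frozenset[str]

    def __post_init__(self) -> None:
        if not (0 <= self.daily_use_normal <= self.daily_use_overuse <= 24):
            raise ValidationError(
                f"{self.product_category}: need 0 <= normal ({self.daily_use_normal}) "
                f"<= overuse ({self.daily_use_overuse}) <= 24 h/d"
            )
        bad = set(self.pathways) - VALID_PATHWAYS
        if bad:
            raise ValidationError(f"{self.product_category}: unknown pathways {sorted(bad)}")
        if not self.pathways:
            raise ValidationError(f"{self.product_category}: pathways must be non-empty")

    def daily_hours(self, usage_mode: str) -> float:
        if usage_mode == "normal":
            return self.daily_use_normal
        if usage_mode == "overuse":
            return self.daily_use_overuse
        raise ValidationError(f"unknown usage mode {usage_mode!r}")

    def clock(self, days_per_year: int = DEFAULT_DAYS_PER_YEAR) -> "ExposureClock":
        return ExposureClock(
            days_per_year=days_per_year,
            annual_hours_normal=annual_exposure_hours(self.daily_use_normal, days_per_year),
            annual_hours_overuse=annual_exposure_hours(self.daily_use_overuse, days_per_year),
        )


@dataclass(frozen=True)
class ExposureClock:
    """Annual exposure hours for both usage modes."""

    days_per_year: int
    annual_hours_normal: float
    annual_hours_overuse: float

    def hours(self, usage_mode: str) -> float:
        if usage_mode == "normal":
            return self.annual_hours_normal
        if usage_mode == "overuse":
            return self.annual_hours_overuse
        raise ValidationError(f"unknown usage mode {usage_mode!r}")


def annual_exposure_hours(daily_hours: float, days_per_year: int = DEFAULT_DAYS_PER_YEAR) -> float:
    """Convert daily usage hours into annual exposure hours (h/y)."""
    if not (0 <= daily_hours <= 24):
        raise ValidationError(f"daily hours must lie in [0, 24], got {daily_hours}")
    if not (1 <= days_per_year <= 366):
        raise ValidationError(f"days_per_year must lie in [1, 366], got {days_per_year}")
    return daily_hours * days_per_year


def load_scenarios(path: str | Path | None = None) -> list[UsageScenario]:
    """Load the usage-scenario table (default: the ten packaged categories).

    Published times exceeding 24 h/d are clamped with a
    :class:`~normdose.errors.DataQualityWarning`; an overuse time shorter than
    the normal time is a :class:`~normdose.errors.ValidationError`.
    """
    if path is None:
        path = Path(str(resources.files("normdose").joinpath("data", "scenarios.csv")))
    df = pd.read_csv(path)
    scenarios = []
    for row in df.itertuples(index=False):
        try:
            normal = parse_duration(row.normal_time)
            overuse = parse_duration(row.overuse_time)
        except FormatError as exc:
            raise FormatError(f"row {row.category!r}: {exc}") from exc
        if overuse < normal:
            raise ValidationError(
                f"row {row.category!r}: overuse time {overuse} h < normal time {normal} h"
            )
        for label, value in (("normal", normal), ("overuse", overuse)):
            if value > 24:
                warnings.warn(
                    f"{row.category}: {label} usage time {value} h/d exceeds a physical "
                    f"day; clamped to 24 h/d",
                    DataQualityWarning,
                    stacklevel=2,
                )
        normal = min(normal, 24.0)
        overuse = min(overuse, 24.0)
        scenarios.append(
            UsageScenario(
                product_category=str(row.category),
                eu_classification=str(row.eu_class),
                usage_location=str(row.location),
                daily_use_normal=normal,
                daily_use_overuse=overuse,
                pathways=frozenset(p.strip() for p in str(row.pathways).split(";") if p.strip()),
            )
        )
    return scenarios
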