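"""Boxplot normalization of activity-concentration surveys.

Measured activity concentrations of a product category are right-skewed with
occasional extreme values, so a survey is summarized by a Tukey boxplot:
quartiles by linear interpolation between order statistics at rank
``1 + p*(n - 1)``, whiskers at the most extreme data points within 1.5·IQR of
the nearest quartile, and everything beyond the fences reported as outliers.
The lower-whisker / median / upper-whisker triple per nuclide then serves as
the standardized ("normalized") concentration input for dose assessment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CompletenessError, ValidationError
from .nuclide_params import NUCLIDE_SYMBOLS

#: Tukey fence multiplier on the interquartile range.
WHISKER_IQR_FACTOR = 1.5

#: The three standardized concentration levels used as assessment inputs.
ASSESSMENT_LEVELS: tuple[str, ...] = ("lower_whisker", "median", "upper_whisker")


@dataclass(frozen=True)
class ConcentrationSurvey:
    """Measured activity concentrations (Bq/g) of one nuclide in one product category."""

    product_category: str
    nuclide: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.nuclide not in NUCLIDE_SYMBOLS:
            raise ValidationError(f"unknown nuclide {self.nuclide!r}")
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))


@dataclass(frozen=True)
class BoxplotSummary:
    """Five-number + whisker/outlier decomposition of a survey (all Bq/g)."""

    lower_whisker: float
    q1: float
    median: float
    q3: float
    upper_whisker: float
    outliers: tuple[float, ...]

    def __post_init__(self) -> None:
        stats = (self.lower_whisker, self.q1, self.median, self.q3, self.upper_whisker)
        if any(a > b for a, b in zip(stats, stats[1:])):
            raise ValidationError(f"boxplot statistics must be non-decreasing, got {stats}")

    def level(self, name: str) -> float:
        """Return the named assessment-level statistic."""
        if name not in ASSESSMENT_LEVELS:
            raise ValidationError(f"unknown level {name!r}; expected one of {ASSESSMENT_LEVELS}")
        return getattr(self, name)


@dataclass(frozen=True)
class ConcentrationSet:
    """One standardized assessment input: nuclide → Bq/g at a single level."""

    level: str
    concentrations: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = [n for n in NUCLIDE_SYMBOLS if n not in self.concentrations]
        if missing:
            raise CompletenessError(f"concentration set missing nuclides {missing}")
        if any(v < 0 for v in self.concentrations.values()):
            raise ValidationError("activity concentrations must be non-negative")
        object.__setattr__(self, "concentrations", dict(self.concentrations))

    def __getitem__(self, nuclide: str) -> float:
        return self.concentrations[nuclide]


def boxplot_summary(survey: ConcentrationSurvey) -> BoxplotSummary:
    """Compute the Tukey boxplot decomposition of a survey.

    Raises
    ------
    ValidationError
        If the survey is empty or contains a negative concentration.
    """
    values = np.asarray(survey.values, dtype=float)
    if values.size == 0:
        raise ValidationError(
            f"empty survey for ({survey.product_category}, {survey.nuclide})"
        )
    if np.any(values < 0):
        raise ValidationError("activity concentrations must be non-negative")

    q1, median, q3 = np.percentile(values, [25, 50, 75], method="linear")
    iqr = q3 - q1
    lo_fence = q1 - WHISKER_IQR_FACTOR * iqr
    hi_fence = q3 + WHISKER_IQR_FACTOR * iqr
    in_fence = values[(values >= lo_fence) & (values <= hi_fence)]
    # Whiskers are the most extreme in-fence data points, clamped to the box
    # edge when no in-fence datum lies beyond the quartile (ties at the
    # quartile can push the interpolated quartile outside the in-fence range;
    # the clamp is the standard plotting convention for that degenerate case).
    lower_whisker = min(float(in_fence.min()), float(q1))
    upper_whisker = max(float(in_fence.max()), float(q3))
    outliers = tuple(sorted(float(v) for v in values[(values < lo_fence) | (values > hi_fence)]))
    return BoxplotSummary(
        lower_whisker=lower_whisker,
        q1=float(q1),
        median=float(median),
        q3=float(q3),
        upper_whisker=upper_whisker,
        outliers=outliers,
    )


def assessment_levels(
    summaries: Mapping[str, BoxplotSummary],
) -> dict[str, ConcentrationSet]:
    """Pair like-with-like whisker statistics across nuclides into assessment inputs.

    Parameters
    ----------
    summaries
        Mapping nuclide → :class:`BoxplotSummary` for one product category;
        must cover all three nuclides.

    Returns
    -------
    dict
        ``{"lower_whisker": ConcentrationSet, "median": ..., "upper_whisker": ...}``
    """
    missing = [n for n in NUCLIDE_SYMBOLS if n not in summaries]
    if missing:
        raise CompletenessError(f"summaries missing for nuclides {missing}")
    return {
        lvl: ConcentrationSet(
            level=lvl,
            concentrations={n: summaries[n].level(lvl) for n in NUCLIDE_SYMBOLS},
        )
        for lvl in ASSESSMENT_LEVELS
    }


# --------------------------------------------------------------------------
# Survey table I/O (long format: product_category, nuclide, activity_bq_per_g)
# --------------------------------------------------------------------------

def read_survey_table(path: str | Path) -> list[ConcentrationSurvey]:
    """Read a long-format survey CSV into per-(category, nuclide) surveys."""
    df = pd.read_csv(path)
    required = {"product_category", "nuclide", "activity_bq_per_g"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"survey table must have columns {sorted(required)}, got {list(df.columns)}"
        )
    surveys = []
    for (cat, nuc), group in df.groupby(["product_category", "nuclide"], sort=True):
        surveys.append(
            ConcentrationSurvey(
                product_category=str(cat),
                nuclide=str(nuc),
                values=tuple(group["activity_bq_per_g"].astype(float)),
            )
        )
    return surveys


def summaries_frame(surveys: Iterable[ConcentrationSurvey]) -> pd.DataFrame:
    """Boxplot-summarize each survey into one tidy row per (category, nuclide)."""
    rows = []
    for survey in surveys:
        s = boxplot_summary(survey)
        rows.append(
            {
                "product_category": survey.product_category,
                "nuclide": survey.nuclide,
                "n": len(survey.values),
                "lower_whisker": s.lower_whisker,
                "q1": s.q1,
                "median": s.median,
                "q3": s.q3,
                "upper_whisker": s.upper_whisker,
                "n_outliers": len(s.outliers),
            }
        )
    return pd.DataFrame(rows).sort_values(["product_category", "nuclide"]).reset_index(drop=True)


def levels_from_surveys(
    surveys: Sequence[ConcentrationSurvey],
) -> dict[str, dict[str, ConcentrationSet]]:
    """Group surveys by category and derive the three assessment levels for each."""
    by_category: dict[str, dict[str, BoxplotSummary]] = {}
    for survey in surveys:
        by_category.setdefault(survey.product_category, {})[survey.nuclide] = boxplot_summary(
            survey
        )
    return {cat: assessment_levels(summaries) for cat, summaries in sorted(by_category.items())}
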