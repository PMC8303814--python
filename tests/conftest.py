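"""Shared fixtures and independent brute-force oracles.

The oracle implementations here deliberately avoid the code paths they check:
quantiles are interpolated by hand on sorted lists, and pathway doses are
multiplied with exact `fractions.Fraction` arithmetic.
"""

from __future__ import annotations

import warnings
from fractions import Fraction

import pytest

from normdose import load_breathing_rates, load_coefficient_table, load_scenarios
from normdose.errors import DataQualityWarning


@pytest.fixture(scope="session")
def coefficient_table():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DataQualityWarning)
        return load_coefficient_table()


@pytest.fixture(scope="session")
def breathing_rates():
    return load_breathing_rates()


@pytest.fixture(scope="session")
def scenarios():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DataQualityWarning)
        return load_scenarios()


# --------------------------------------------------------------------------
# Brute-force boxplot oracle: stated quantile and fence definitions, by hand
# --------------------------------------------------------------------------

def _quantile_by_rank(sorted_values: list[float], p: float) -> float:
    """Linear interpolation at rank 1 + p*(n-1) on a pre-sorted list."""
    n = len(sorted_values)
    rank = p * (n - 1)  # 0-based
    lo = int(rank)
    hi = min(lo + 1, n - 1)
    frac = rank - lo
    return sorted_values[lo] * (1 - frac) + sorted_values[hi] * frac


def brute_force_boxplot(values) -> dict:
    """Independent Tukey decomposition: sort, interpolate, scan the fences."""
    s = sorted(float(v) for v in values)
    q1 = _quantile_by_rank(s, 0.25)
    median = _quantile_by_rank(s, 0.50)
    q3 = _quantile_by_rank(s, 0.75)
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = [v for v in s if lo_fence <= v <= hi_fence]
    outliers = [v for v in s if v < lo_fence or v > hi_fence]
    # same degenerate-tie convention as the implementation under test: a
    # whisker never retreats inside the box (clamped to the quartile)
    return {
        "lower_whisker": min(min(inside), q1),
        "q1": q1,
        "median": median,
        "q3": q3,
        "upper_whisker": max(max(inside), q3),
        "outliers": tuple(outliers),
    }


@pytest.fixture(scope="session")
def boxplot_oracle():
    return brute_force_boxplot


# --------------------------------------------------------------------------
# Exact-arithmetic pathway-dose oracle
# --------------------------------------------------------------------------

def exact_product(*factors) -> float:
    """Multiply factors exactly with Fraction arithmetic, then convert once."""
    acc = Fraction(1)
    for f in factors:
        acc *= Fraction(f)
    return float(acc)


@pytest.fixture(scope="session")
def dose_oracle():
    return exact_product
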