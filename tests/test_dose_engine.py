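"""Dose engine: pathway products, TEDE additivity, scenario assessment, limit."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from normdose import (
    ConcentrationSet,
    DoseBreakdown,
    ExposureAssumptions,
    UsageScenario,
    assess,
    compare_to_limit,
    external_dose,
    ingestion_dose,
    inhalation_dose,
    total_dose,
)
from normdose.errors import ConfigurationError, ValidationError

NECKLACE_HOURS = (8 + 7 / 60) * 365  # 2962.58 h/y


def _scenario(pathways=("external", "inhalation", "ingestion")):
    return UsageScenario(
        product_category="necklace",
        eu_classification="Existing Products",
        usage_location="Neck",
        daily_use_normal=8 + 7 / 60,
        daily_use_overuse=10 + 7 / 60,
        pathways=frozenset(pathways),
    )


def _level(u=4.21, th=24.1, k=0.55, name="upper_whisker"):
    return ConcentrationSet(name, {"U-238": u, "Th-232": th, "K-40": k})


class TestPathwayProducts:
    def test_external_zero_source_and_unit_identity(self):
        assert external_dose(0.0, 1234.0, 5e-13) == 0.0
        assert external_dose(1.0, 1.0, 1.0) == 1.0

    def test_external_hand_product(self):
        # K-40 necklace upper whisker through the adult external coefficient
        got = external_dose(0.55, NECKLACE_HOURS, 3.46e-13)
        assert got == pytest.approx(5.638e-10, rel=1e-3)

    def test_inhalation_hand_product(self):
        # literal screening formula: Th-232 upper whisker, infant air-mass rate
        got = inhalation_dose(24.1, 260.0, NECKLACE_HOURS, 8.1e-5, 1.0)
        assert got == pytest.approx(1.5035e3, rel=1e-3)

    def test_inhalation_zero_transfer_factor_kills_dose(self):
        assert inhalation_dose(24.1, 260.0, NECKLACE_HOURS, 8.1e-5, 0.0) == 0.0

    def test_ingestion_hand_product(self):
        got = ingestion_dose(0.55, 0.01, NECKLACE_HOURS, 6.2e-9)
        assert got == pytest.approx(1.010e-7, rel=1e-3)

    @pytest.mark.parametrize(
        "fn, args",
        [
            (external_dose, (-1.0, 1.0, 1.0)),
            (external_dose, (1.0, -1.0, 1.0)),
            (inhalation_dose, (1.0, 1.0, -1.0, 1.0, 1.0)),
            (ingestion_dose, (1.0, 1.0, 1.0, -1.0)),
        ],
    )
    def test_negative_inputs_rejected(self, fn, args):
        with pytest.raises(ValidationError):
            fn(*args)

    def test_transfer_factor_above_one_rejected(self):
        with pytest.raises(ValidationError):
            inhalation_dose(1.0, 1.0, 1.0, 1.0, 1.5)

    @settings(deadline=None, max_examples=200)
    @given(
        c=st.floats(0, 100, allow_nan=False),
        t=st.floats(0, 8760, allow_nan=False),
        dcf=st.floats(0, 1e-3, allow_nan=False),
        k=st.floats(0.1, 10, allow_nan=False),
    )
    def test_linearity_in_every_factor(self, c, t, dcf, k):
        base = external_dose(c, t, dcf)
        assert external_dose(k * c, t, dcf) == pytest.approx(k * base, rel=1e-12, abs=1e-300)
        assert external_dose(c, k * t, dcf) == pytest.approx(k * base, rel=1e-12, abs=1e-300)
        assert external_dose(c, t, k * dcf) == pytest.approx(k * base, rel=1e-12, abs=1e-300)

    def test_matches_exact_arithmetic_oracle(self, dose_oracle):
        for c in (1, 2, 5):
            for rate in (1, 260, 775):
                for hours in (1, 100, 8760):
                    for dcf in (1e-9, 1e-5):
                        assert inhalation_dose(c, rate, hours, dcf, 1.0) == pytest.approx(
                            dose_oracle(c, rate, hours, dcf), rel=1e-15
                        )
                        assert ingestion_dose(c, rate, hours, dcf) == pytest.approx(
                            dose_oracle(c, rate, hours, dcf), rel=1e-15
                        )
                    assert external_dose(c, hours, 1e-13) == pytest.approx(
                        dose_oracle(c, hours, 1e-13), rel=1e-15
                    )


class TestTotalDose:
    def test_additivity_and_unit_conversion(self):
        bd = total_dose(
            {"U-238": 1e-4}, {"Th-232": 9e-4}, {"K-40": 0.0},
            age="adult", usage_mode="normal", level="median",
        )
        assert bd.external == pytest.approx(0.1)
        assert bd.inhalation == pytest.approx(0.9)
        assert bd.total == pytest.approx(1.0, rel=1e-12)
        assert sum(bd.per_nuclide_total.values()) == pytest.approx(bd.total, rel=1e-12)

    def test_all_zero(self):
        bd = total_dose({}, {}, {}, age="adult", usage_mode="normal", level="median")
        assert bd.total == 0.0

    def test_breakdown_invariants(self):
        with pytest.raises(ValidationError):
            DoseBreakdown(external=1.0, inhalation=1.0, ingestion=0.0, total=5.0,
                          age="adult", usage_mode="normal", level="median")
        with pytest.raises(ValidationError):
            DoseBreakdown(external=-1.0, inhalation=0.0, ingestion=0.0, total=-1.0,
                          age="adult", usage_mode="normal", level="median")


class TestAssess:
    def test_zero_concentrations_give_zero_breakdown(self, coefficient_table, breathing_rates):
        bd = assess(
            _scenario(), _level(0, 0, 0), "adult", coefficient_table,
            ExposureAssumptions(ingestion_rate=0.01), breathing_rates=breathing_rates,
        )
        assert bd.total == 0.0

    def test_linearity_in_concentration(self, coefficient_table, breathing_rates):
        kwargs = dict(
            age="one_year_old", table=coefficient_table,
            assumptions=ExposureAssumptions(ingestion_rate=0.005),
            breathing_rates=breathing_rates,
        )
        base = assess(_scenario(), _level(), **kwargs)
        doubled = assess(_scenario(), _level(8.42, 48.2, 1.1), **kwargs)
        for name in ("external", "inhalation", "ingestion", "total"):
            assert getattr(doubled, name) == pytest.approx(2 * getattr(base, name), rel=1e-12)

    def test_overuse_dominates_normal(self, coefficient_table, breathing_rates):
        kwargs = dict(
            age="adult", table=coefficient_table,
            assumptions=ExposureAssumptions(ingestion_rate=0.005),
            breathing_rates=breathing_rates,
        )
        normal = assess(_scenario(), _level(), usage_mode="normal", **kwargs)
        overuse = assess(_scenario(), _level(), usage_mode="overuse", **kwargs)
        for name in ("external", "inhalation", "ingestion", "total"):
            assert getattr(overuse, name) >= getattr(normal, name)
        assert overuse.total > normal.total

    def test_inactive_pathways_contribute_zero(self, coefficient_table, breathing_rates):
        bd = assess(
            _scenario(pathways=("ingestion",)), _level(), "adult", coefficient_table,
            ExposureAssumptions(ingestion_rate=0.01), breathing_rates=breathing_rates,
        )
        assert bd.external == 0.0 and bd.inhalation == 0.0 and bd.ingestion > 0.0

    def test_report_all_pathways_flag(self, coefficient_table, breathing_rates):
        bd = assess(
            _scenario(pathways=("ingestion",)), _level(), "adult", coefficient_table,
            ExposureAssumptions(ingestion_rate=0.0), breathing_rates=breathing_rates,
            report_all_pathways=True,
        )
        assert bd.external > 0.0 and bd.inhalation > 0.0

    def test_missing_absorption_policy_entry(self, coefficient_table, breathing_rates):
        with pytest.raises(ConfigurationError, match="U-238"):
            assess(
                _scenario(), _level(), "adult", coefficient_table,
                ExposureAssumptions(ingestion_rate=0.0),
                absorption_policy={"K-40": "F"}, breathing_rates=breathing_rates,
            )

    def test_level_monotonicity(self, coefficient_table, breathing_rates):
        kwargs = dict(
            age="ten_year_old", table=coefficient_table,
            assumptions=ExposureAssumptions(ingestion_rate=0.002),
            breathing_rates=breathing_rates,
        )
        lower = assess(_scenario(), _level(0.5, 3.0, 0.1, "lower_whisker"), **kwargs)
        median = assess(_scenario(), _level(1.5, 9.0, 0.2, "median"), **kwargs)
        upper = assess(_scenario(), _level(4.21, 24.1, 0.55, "upper_whisker"), **kwargs)
        assert lower.total <= median.total <= upper.total


class TestLimitComparison:
    @pytest.mark.parametrize(
        "total, verdict", [(2.03, "exceeds"), (0.5, "below"), (1.0, "below")]
    )
    def test_strict_screening(self, total, verdict):
        bd = DoseBreakdown(external=0.0, inhalation=total, ingestion=0.0, total=total,
                           age="adult", usage_mode="normal", level="upper_whisker")
        v = compare_to_limit(bd)
        assert v.verdict == verdict
        assert v.margin_msv == pytest.approx(total - 1.0)

    def test_exposure_assumption_validation(self):
        with pytest.raises(ValidationError):
            ExposureAssumptions(ingestion_rate=-0.1)
        with pytest.raises(ValidationError):
            ExposureAssumptions(ingestion_rate=0.0, air_transfer_factor=1.5)
        with pytest.raises(ValidationError):
            ExposureAssumptions(ingestion_rate=0.0, ingestion_hours=9000)
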