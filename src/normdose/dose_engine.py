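"""Annual external, inhalation and ingestion doses and their total (TEDE).

For a nuclide with activity concentration C (Bq/g) in a product the three
pathway doses per year are plain multiplicative screening models:

    external (Sv/y)   =  C × ET × DCF_ext          ET: annual exposure h/y,
                                                   DCF_ext: Sv/h per Bq/g
    inhalation (Sv/y) =  C × IR_inh × Ht × DCF_inh × f_air
                                                   IR_inh: breathed air mass g/h,
                                                   Ht: h/y, DCF_inh: Sv/Bq
    ingestion (Sv/y)  =  C × IR_ing × IT × DCF_ing IR_ing: inadvertently
                                                   ingested mass g/h, IT: h/y

and the total effective dose equivalent (TEDE) is their sum over all pathways
and nuclides, reported in mSv/y and screened against the ICRP public dose
limit of 1 mSv/y.

``f_air`` (``air_transfer_factor``) is a dimensionless dilution factor in
[0, 1] scaling the inhaled-mass term: at its default of 1 the inhalation model
applies the product's activity concentration to the whole breathed air mass
(the literal screening formula, maximally conservative); values below 1
represent the fraction of breathed air mass actually bearing product-derived
activity.  Every report records the factor used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .concentration_stats import ConcentrationSet
from .errors import ConfigurationError, ValidationError
from .nuclide_params import (
    AGE_GROUPS,
    INHALATION_TYPES,
    NUCLIDE_SYMBOLS,
    AgeParameters,
    DoseCoefficientTable,
    load_breathing_rates,
    lookup_dcf,
)
from .scenario_model import DEFAULT_DAYS_PER_YEAR, UsageScenario

#: ICRP-recommended annual effective dose limit for members of the public.
PUBLIC_DOSE_LIMIT_MSV_PER_Y = 1.0

MSV_PER_SV = 1000.0

USAGE_MODES: tuple[str, ...] = ("normal", "overuse")

#: Default absorption-type selection when the chemical form is unknown:
#: type M (moderate solubilization) is the conventional screening default for
#: particulates; K-40 is tabulated with type F only.
DEFAULT_ABSORPTION_POLICY: Mapping[str, str] = {"U-238": "M", "Th-232": "M", "K-40": "F"}


@dataclass(frozen=True)
class ExposureAssumptions:
    """Intake assumptions that the published scenario table does not fix.

    ``ingestion_rate`` (g/h of product mass inadvertently ingested) has no
    published value and must be supplied explicitly; 0 disables the pathway.
    ``ingestion_hours`` defaults to the scenario's annual exposure hours when
    ``None``.
    """

    ingestion_rate: float
    ingestion_hours: float | None = None
    air_transfer_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.ingestion_rate < 0:
            raise ValidationError("ingestion_rate must be >= 0")
        if self.ingestion_hours is not None and not (0 <= self.ingestion_hours <= 8784):
            raise ValidationError("ingestion_hours must lie in [0, 8784]")
        if not (0 <= self.air_transfer_factor <= 1):
            raise ValidationError("air_transfer_factor must lie in [0, 1]")


@dataclass(frozen=True)
class DoseBreakdown:
    """Per-pathway annual doses (mSv/y) and their TEDE for one assessment cell."""

    external: float
    inhalation: float
    ingestion: float
    total: float
    age: str
    usage_mode: str
    level: str
    per_nuclide_total: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("external", "inhalation", "ingestion"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} dose must be >= 0")
        component_sum = self.external + self.inhalation + self.ingestion
        if abs(self.total - component_sum) > 1e-12 * max(component_sum, 1.0):
            raise ValidationError(
                f"total {self.total} != sum of components {component_sum}"
            )


@dataclass(frozen=True)
class LimitVerdict:
    """Comparison of a TEDE against an annual dose limit."""

    verdict: str  # "below" | "exceeds"
    margin_msv: float  # total - limit (positive when exceeding)
    limit_msv: float


def _check_non_negative(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if value < 0:
            raise ValidationError(f"{name} must be >= 0, got {value}")


def external_dose(concentration: float, exposure_hours: float, dcf_external: float) -> float:
    """Annual external dose (Sv/y) from direct gamma exposure to the product."""
    _check_non_negative(
        concentration=concentration, exposure_hours=exposure_hours, dcf_external=dcf_external
    )
    return concentration * exposure_hours * dcf_external


def inhalation_dose(
    concentration: float,
    breathing_mass_rate: float,
    exposure_hours: float,
    dcf_inh: float,
    air_transfer_factor: float = 1.0,
) -> float:
    """Annual committed dose (Sv/y) from inhaling product-derived activity."""
    _check_non_negative(
        concentration=concentration,
        breathing_mass_rate=breathing_mass_rate,
        exposure_hours=exposure_hours,
        dcf_inh=dcf_inh,
        air_transfer_factor=air_transfer_factor,
    )
    if air_transfer_factor > 1:
        raise ValidationError("air_transfer_factor must be <= 1")
    return concentration * breathing_mass_rate * exposure_hours * dcf_inh * air_transfer_factor


def ingestion_dose(
    concentration: float, ingestion_rate: float, ingestion_hours: float, dcf_ing: float
) -> float:
    """Annual committed dose (Sv/y) from inadvertent ingestion of product mass."""
    _check_non_negative(
        concentration=concentration,
        ingestion_rate=ingestion_rate,
        ingestion_hours=ingestion_hours,
        dcf_ing=dcf_ing,
    )
    return concentration * ingestion_rate * ingestion_hours * dcf_ing


def total_dose(
    external_by_nuclide: Mapping[str, float],
    inhalation_by_nuclide: Mapping[str, float],
    ingestion_by_nuclide: Mapping[str, float],
    *,
    age: str,
    usage_mode: str,
    level: str,
) -> DoseBreakdown:
    """Sum per-nuclide pathway doses (Sv/y) into a TEDE breakdown in mSv/y."""
    pathway_maps = {
        "external": external_by_nuclide,
        "inhalation": inhalation_by_nuclide,
        "ingestion": ingestion_by_nuclide,
    }
    for pathway, mapping in pathway_maps.items():
        for nuc, value in mapping.items():
            if value < 0:
                raise ValidationError(f"{pathway} dose for {nuc} must be >= 0")

    ext = sum(external_by_nuclide.values()) * MSV_PER_SV
    inh = sum(inhalation_by_nuclide.values()) * MSV_PER_SV
    ing = sum(ingestion_by_nuclide.values()) * MSV_PER_SV
    nuclides = set(external_by_nuclide) | set(inhalation_by_nuclide) | set(ingestion_by_nuclide)
    per_nuclide = {
        nuc: (
            external_by_nuclide.get(nuc, 0.0)
            + inhalation_by_nuclide.get(nuc, 0.0)
            + ingestion_by_nuclide.get(nuc, 0.0)
        )
        * MSV_PER_SV
        for nuc in sorted(nuclides)
    }
    return DoseBreakdown(
        external=ext,
        inhalation=inh,
        ingestion=ing,
        total=ext + inh + ing,
        age=age,
        usage_mode=usage_mode,
        level=level,
        per_nuclide_total=per_nuclide,
    )


def assess(
    scenario: UsageScenario,
    level: ConcentrationSet,
    age: str,
    table: DoseCoefficientTable,
    assumptions: ExposureAssumptions,
    usage_mode: str = "normal",
    absorption_policy: Mapping[str, str] | None = None,
    *,
    breathing_rates: Mapping[str, AgeParameters] | None = None,
    days_per_year: int = DEFAULT_DAYS_PER_YEAR,
    report_all_pathways: bool = False,
) -> DoseBreakdown:
    """Full multi-nuclide assessment of one (scenario, level, age, mode) cell.

    Pathways absent from the scenario contribute zero unless
    ``report_all_pathways`` is set (screening reports conventionally evaluate
    the external pathway for every product even where it is secondary).

    Raises
    ------
    ConfigurationError
        If the absorption policy omits a nuclide that has several tabulated
        absorption types.
    """
    if age not in AGE_GROUPS:
        raise ValidationError(f"unknown age group {age!r}")
    policy = dict(DEFAULT_ABSORPTION_POLICY if absorption_policy is None else absorption_policy)
    for nuc in NUCLIDE_SYMBOLS:
        if len(INHALATION_TYPES[nuc]) == 1:
            policy.setdefault(nuc, INHALATION_TYPES[nuc][0])
        elif nuc not in policy:
            raise ConfigurationError(
                f"absorption policy missing {nuc}, which has types {INHALATION_TYPES[nuc]}"
            )
    if breathing_rates is None:
        breathing_rates = load_breathing_rates()

    hours = scenario.clock(days_per_year).hours(usage_mode)
    ing_hours = assumptions.ingestion_hours if assumptions.ingestion_hours is not None else hours
    active = (
        set(scenario.pathways)
        if not report_all_pathways
        else {"external", "inhalation", "ingestion"}
    )

    ext: dict[str, float] = {}
    inh: dict[str, float] = {}
    ing: dict[str, float] = {}
    for nuc in NUCLIDE_SYMBOLS:
        conc = level[nuc]
        ext[nuc] = (
            external_dose(conc, hours, lookup_dcf(table, nuc, age, "external"))
            if "external" in active
            else 0.0
        )
        inh[nuc] = (
            inhalation_dose(
                conc,
                breathing_rates[age].inhalation_mass_per_hour,
                hours,
                lookup_dcf(table, nuc, age, "inhalation", policy[nuc]),
                assumptions.air_transfer_factor,
            )
            if "inhalation" in active
            else 0.0
        )
        ing[nuc] = (
            ingestion_dose(
                conc,
                assumptions.ingestion_rate,
                ing_hours,
                lookup_dcf(table, nuc, age, "ingestion"),
            )
            if "ingestion" in active
            else 0.0
        )
    return total_dose(ext, inh, ing, age=age, usage_mode=usage_mode, level=level.level)


def compare_to_limit(
    breakdown: DoseBreakdown, limit: float = PUBLIC_DOSE_LIMIT_MSV_PER_Y
) -> LimitVerdict:
    """Screen a TEDE against an annual limit (strict: exceeds iff total > limit)."""
    verdict = "exceeds" if breakdown.total > limit else "below"
    return LimitVerdict(verdict=verdict, margin_msv=breakdown.total - limit, limit_msv=limit)
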