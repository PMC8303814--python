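# normdose

Screening-level radiological dose assessment for members of the public using
consumer products that contain naturally occurring radioactive materials
(NORM): monazite- or zircon-bearing pillows, mattresses, jewelry, patches,
cosmetics and similar goods whose activity comes from ²³⁸U, ²³²Th and ⁴⁰K.

The package implements the full assessment chain as a tested, reusable
pipeline:

1. **Boxplot normalization** — per-category activity-concentration surveys
   (Bq/g) are reduced to a Tukey five-number summary; the lower whisker,
   median and upper whisker become the three standardized assessment inputs.
2. **Usage scenarios** — ten product categories with daily usage times for
   normal use and overuse (normal + 2 h) and their exposure pathways; daily
   times convert to annual exposure hours.
3. **Dose engine** — age-dependent annual doses per pathway and their total
   effective dose equivalent (TEDE), screened against the ICRP public dose
   limit of 1 mSv/y:

   ```
   D_ext  [Sv/y] = C · ET · DCF_ext                      (external gamma)
   D_inh  [Sv/y] = C · IR_inh · Ht · DCF_inh · f_air     (inhalation)
   D_ing  [Sv/y] = C · IR_ing · IT · DCF_ing             (inadvertent ingestion)
   TEDE [mSv/y]  = Σ_pathways Σ_nuclides D
   ```

   with C the activity concentration (Bq/g), ET/Ht/IT annual exposure hours,
   IR_inh the age-dependent breathed air mass (g/h), IR_ing the inadvertent
   ingestion rate (g/h), DCF the ICRP dose coefficients (Sv/Bq, or Sv/h per
   Bq/g for the external pathway) and f_air ∈ [0, 1] an air-transfer factor
   (1 = the literal, maximally conservative screening formula).

Dose coefficients (ICRP Publications 119 and 144, age groups 1 y / 10 y /
adult, inhalation keyed by absorption type F/M/S) and breathing rates ship as
audited CSV fixtures; two known transcription anomalies are flagged with
`DataQualityWarning` at load time. A seeded lognormal survey generator stands
in for undeposited survey data so the whole pipeline runs and is testable
offline.

## Worked example

Screen a necklace at its upper-whisker activity concentrations
(4.21 Bq/g ²³⁸U, 24.1 Bq/g ²³²Th, 0.55 Bq/g ⁴⁰K) for an adult, normal use
(8 h 7 min/day, 365 d/y):

```python
from normdose import (ConcentrationSet, ExposureAssumptions, assess,
                      compare_to_limit, load_breathing_rates,
                      load_coefficient_table, load_scenarios)

table = load_coefficient_table()          # warns about two audited anomalies
necklace = next(s for s in load_scenarios() if s.product_category == "necklace")
level = ConcentrationSet("upper_whisker",
                         {"U-238": 4.21, "Th-232": 24.1, "K-40": 0.55})
bd = assess(necklace, level, "adult", table,
            ExposureAssumptions(ingestion_rate=0.0),
            breathing_rates=load_breathing_rates(), report_all_pathways=True)
print(f"external   {bd.external:.3e} mSv/y")
print(f"inhalation {bd.inhalation:.3e} mSv/y")
print(f"total      {bd.total:.3e} mSv/y")
print(compare_to_limit(bd))
```

prints

```
external   5.890e-07 mSv/y
inhalation 3.682e+06 mSv/y
total      3.682e+06 mSv/y
LimitVerdict(verdict='exceeds', margin_msv=3681646.2742316327, limit_msv=1.0)
```

The external gamma dose is tiny (⁴⁰K contributes only 11% gamma decays); the
inhalation term dominates — and at `air_transfer_factor = 1` it is enormous,
because the literal screening formula assumes every gram of breathed air
carries the product's full activity concentration. Realistic screening sets
`ExposureAssumptions(air_transfer_factor=...)` to the airborne-release
fraction for the product; every report records the factor used. See
`docs/methods.md` for the model's assumptions and limitations.

## Command line

```sh
normdose simulate --seed 42 --out surveys.csv        # synthetic survey table
normdose stats --surveys surveys.csv --out stats/    # boxplot summaries only
normdose assess --config run.yaml                    # full pipeline
```

`normdose assess` writes `assessments.csv`/`.json` (one row per
category × age × usage mode × level, with per-pathway doses in mSv/y and the
limit verdict), `boxplot_summaries.csv`, a human-readable `report.txt` and a
`provenance.json` recording fixture checksums, the absorption policy, the
air-transfer factor and every data-quality warning raised during the run.

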