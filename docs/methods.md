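# Methods

## Model

`normdose` performs screening-level (conservative, multiplicative) dose
assessment for consumer products containing the primordial radionuclides
²³⁸U, ²³²Th and ⁴⁰K. Three exposure pathways are modelled for three age
groups (1 year old, 10 years old, adult), per product category, usage mode
(normal / overuse) and concentration level (lower whisker / median / upper
whisker of the product's survey):

- **External**: `D_ext = C · ET · DCF_ext`, with C the product's activity
  concentration (Bq/g), ET the annual exposure time (h/y) and DCF_ext the
  age-dependent external dose-rate coefficient (Sv/h per Bq/g, from ICRP
  Publication 144). No geometry, distance or shielding is modelled; the
  coefficient absorbs all of it.
- **Inhalation**: `D_inh = C · IR_inh · Ht · DCF_inh · f_air`, with IR_inh
  the age-dependent breathed air mass (g/h, at air density 1.225 kg/m³), Ht
  the annual hours of exposure to contaminated air and DCF_inh the committed
  effective dose coefficient (Sv/Bq, ICRP Publication 119), selected by
  absorption type (F/M/S).
- **Ingestion**: `D_ing = C · IR_ing · IT · DCF_ing`, with IR_ing an
  inadvertent ingestion rate (g/h) and IT the annual ingestion hours.

The total effective dose equivalent (TEDE) is the sum over pathways and
nuclides, converted to mSv/y only at report construction (all internal
arithmetic is in Sv/y), and screened strictly (`>`) against the ICRP public
dose limit of 1 mSv/y; a total of exactly 1.0 mSv/y reports "below" with zero
margin.

### Assumptions and their consequences

- **Parent nuclides only.** The Table of coefficients covers ²³⁸U, ²³²Th and
  ⁴⁰K themselves; no decay-chain ingrowth, progeny equilibrium or
  radon/thoron emanation is modelled. Real inhalation hazard from these
  products is largely progeny-driven, so this is a structural simplification,
  not a conservatism.
- **The air-transfer factor `f_air`.** The literal inhalation formula
  (`f_air = 1`) applies the product's bulk activity concentration to every
  gram of breathed air — equivalent to breathing pulverized product — and
  yields totals many orders of magnitude above 1 mSv/y for any realistic
  concentration. `f_air` exists to make the dilution explicit: it is the
  fraction of breathed air mass actually bearing product-derived activity.
  Its default stays at 1 (the formula as stated, maximally conservative);
  every result table and provenance record states the value used, and
  screening conclusions at `f_air = 1` should be read as upper bounds only.
- **Occupancy.** Daily usage times convert to annual hours with use on all
  365 days for both normal use and overuse (`days_per_year` is
  configurable, 1–366). Overuse adds 2 h/day to every category.
- **Ingestion rate.** No authoritative inadvertent-ingestion rate exists for
  these products; `ExposureAssumptions.ingestion_rate` is therefore a
  required input with no default (0 disables the pathway), and ingestion
  hours default to the scenario's annual exposure hours.

## Parameters

| Parameter | Units | Default | Why |
|---|---|---|---|
| `days_per_year` | d/y | 365 | annual screening assumption; configurable |
| `air_transfer_factor` | — | 1.0 | literal screening formula; see above |
| `ingestion_rate` | g/h | required (pipeline config: 0.0) | no published value |
| absorption policy | — | M for U-238/Th-232, F for K-40 | M is the conventional particulate default when the chemical form is unknown; K-40 is tabulated with F only |
| dose limit | mSv/y | 1.0 | ICRP public dose limit |
| whisker fence | — | 1.5·IQR | Tukey convention |

## Boxplot normalization

Quartiles use linear interpolation between order statistics at rank
`1 + p·(n − 1)` (the common plotting default; `numpy.percentile`'s "linear"
method). Whiskers sit at the most extreme data points within 1.5·IQR of the
nearest quartile; points beyond the fences are outliers. Degenerate tie case:
when every in-fence datum lies inside the box (possible with heavily tied
data such as `[0, 0, 0, 1]`, where the interpolated q3 exceeds all in-fence
points), the whisker clamps to the quartile — the standard plotting
convention — so the five statistics are always ordered. "Normalized activity
concentration" means exactly these whisker/median statistics used as
standardized inputs; no further rescaling is applied. No distribution
fitting, censoring treatment or hypothesis testing is performed.

## Packaged reference tables

Coefficient and breathing-rate fixtures are diff-able CSVs carried verbatim
from their audited transcription, with three flagged data-quality items:

1. The 10-year-old ²³⁸U inhalation coefficients (7.3e-4 / 4.0e-4 / 1.0e-4
   Sv/Bq) are 2–3 orders of magnitude above the neighbouring age columns.
   They are packaged as published and flagged at load; results for that cell
   inherit the anomaly.
2. The published adult breathed-air mass of 1331.13 g/h contradicts the
   table's own equivalence (0.925 m³/h × 1225 g/m³ = 1133.13 g/h) and is
   packaged as the corrected 1133.13, with the published digit string kept in
   the fixture's comment column.
3. The ²³²Th half-life is carried as published (1.405e1 y; the physical value
   is ~1.405e10 y) and flagged; it enters no equation.

Internal consistency of each breathing-rate triple is enforced at 0.75%
relative — just above the 0.53% rounding of the published 10-year-old m³/h
value, and far below the 17% discrepancy of the transposed adult cell.

The clothing scenario's published overuse time ("1 day 2 h" = 26 h/d) is
clamped to 24 h/d with a load-time warning, since occupancy cannot exceed a
physical day.

## Synthetic surveys

No survey dataset is deposited, so the generator emulates one: per
(category, nuclide), `n` i.i.d. draws from a lognormal — positive,
right-skewed, with occasional fence-crossing outliers, matching the
qualitative structure boxplots of real concentration surveys show. Target
calibration (`spec_from_targets`) sets the log-location to `ln(median)` and
root-finds (Brent, tol 1e-6) the log-scale so the population Tukey upper
fence `2.5·e^{zσ} − 1.5·e^{−zσ}` (z = Φ⁻¹(0.75)) times the median equals the
target upper whisker; at large n the largest in-fence sample point converges
to that fence from below. The default target table pins the necklace upper
whiskers at 4.21 / 24.1 / 0.55 Bq/g (U/Th/K) — the hottest published inputs —
with medians at roughly a third of the whisker, and assigns the other nine
categories plausible lower levels (jewelry and mineral patches hotter than
fabrics and diapers). Default survey size is 400 samples per
(category, nuclide); tests use 1e5–2e5 draws where quantile recovery is
asserted (median within 3%, calibrated whisker within 10%).

What the generator does **not** emulate: detection-limit censoring,
inter-product correlation between nuclides, measurement uncertainty, and any
claim about the true distribution of any real product class. Passing tests
therefore demonstrate correctness of the pipeline's statistics and dose
arithmetic, not the representativeness of the synthetic levels.

Randomness is pinned to numpy's PCG64 `default_rng`; one integer seed per
survey spec, with per-survey seeds spawned deterministically from a single
run seed, so a whole run is byte-for-byte reproducible.

## Numerical choices

- All pathway doses are plain products of non-negative floats; additivity of
  the TEDE is enforced to 1e-12 relative at breakdown construction.
- Breathing-rate unit conversions route through m³/h using 24 h/d and
  1225 g/m³ exactly; round trips are exact to 1e-12 relative.
- Duration parsing accepts "H h M min", "M min", "D day H h" and decimal
  hours; minutes convert at exactly 1/60 h.
- CSV outputs use a fixed `%.10g` float format and JSON outputs sort their
  keys, so repeated runs of the same config are byte-identical.
- Result-report tables round components to six decimals and print each total
  as the sum of its rounded components, so the printed report re-adds at
  displayed precision.

## Known limitations

- Screening only: no organ doses, no voxel-phantom transport, no point-kernel
  gamma shielding, no biokinetic retention modelling.
- The `f_air = 1` default makes inhalation totals upper bounds that can be
  physically absurd for bulk solids; meaningful absolute screening requires a
  product-specific airborne-release fraction.
- The anomalous 10-year-old ²³⁸U inhalation coefficients propagate as
  published; 10-year-old inhalation results for U-238 should not be compared
  across age groups without noting the flag.
- Usage-location metadata (neck, face, whole body, ...) is carried but not
  used geometrically.
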