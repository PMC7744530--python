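# Methods

This note documents the models implemented in `hmrisk`, the defaults they
ship with, the numerical choices made where the field's conventions leave
room, and what the synthetic data generator does and does not emulate.

## Study design the package models

Concentrations of ten metals (Mg, Mn, Ag, Zn, Cd, Pb, Cu, Fe, As, Cr) are
measured in topsoil and well water at a polluted site and at an unpolluted
control location sharing the site's geology. Soil units are mg/kg (ppm for
solids) and water units mg/L (ppm for dilute aqueous solutions); the two are
treated as exactly interchangeable with ppm, which is what guideline
comparison requires. Non-detects ("ND", "NA" or an empty cell, any case) are
carried as flagged records and **excluded** from every statistic — never
imputed, never zero-filled. (A half-detection-limit imputation switch exists
but is off by default; the reference datasets report ND with no imputation
and leave the affected cells blank downstream.) Summary SDs use the sample
(n−1) denominator; this is a conventional choice, not stated by the source
summaries.

## Pollution indices

For each metal with a positive control mean:

- **MEF** (modified enrichment factor) = C_site / C_control. The classical
  enrichment factor divides this again by the same ratio for a conservative
  reference element; that double-ratio form is available via
  `reference_element`, but the plain per-element ratio is the default because
  it is the form the self-consistent reference values follow (for Cd:
  10.05/3.8 = 2.645, with AM = 164.47 % and MPI = 2.91 all mutually
  consistent only under this reading).
- **MPI** (modified pollution index) = sqrt((MEF_mean² + MEF_max²)/2), the
  root-mean-square of the mean-based and maximum-based enrichment factors.
  MEF_mean uses the site *mean* concentration and MEF_max the site *maximum*;
  both divide by the control *mean*.
- **AM** (anthropogenic metal percentage) = 100·(C_site − C_control)/C_control.
  Algebraically AM = 100·(MEF − 1) for the same concentration pair; this
  identity is asserted in the test suite for random inputs.

Classification bands (enrichment: minimal < 2 ≤ moderate < 5 ≤ significant
< 20 ≤ very high < 40 ≤ extremely high; MPI: unpolluted < 1 ≤ slight < 2 ≤
moderate < 3 ≤ significant < 5 ≤ severe < 10 ≤ extreme) are implemented as
half-open intervals `[lower, upper)`. The source rules write strict
inequalities on both sides, which leaves the boundary values undefined; the
half-open convention makes classification total and monotone, which the
tests verify over a log grid.

**Depth attenuation.** For a depth-by-metal profile, the summary per metal
is: the relative decrease 100·(c(0) − c(d*))/c(0) between the surface and the
depth nearest 50 cm, the CV of values below that depth (the plateau), and a
non-strict monotone-decline flag over 0–50 cm. A profile without a surface
(0 cm) level is marked incomplete rather than extrapolated.

## Exposure (average daily intake)

All doses are chronic averages in mg/kg/day for a single adult receptor:

| pathway | equation |
|---|---|
| soil ingestion | Cs·IngRs·10⁻⁶·EF·ED/(BW·AT) |
| water ingestion | Cw·IngRw·EF·ED/(BW·AT) |
| soil-dust inhalation | Cs·InhR·EF·ED/(PEF·BW·AT) |
| soil dermal | Cs·SA·AF·ABS·10⁻⁶·EF·ED/(BW·AT) |
| water dermal | Cw·10⁻³·SA·KP·AF·ABS·ET·EF·ED/(BW·AT) |

The 10⁻⁶ kg/mg factor in the soil-mass pathways converts ingested/adhering
soil mass so that mg(metal)/kg(soil)·mg(soil)/day yields mg/day; it is the
only scaling that reproduces the reference dose tables from the printed
concentrations. In the water-dermal equation, SA (cm²)·KP (cm/h)·ET (h) is a
water volume in cm³, so the 10⁻³ L/cm³ factor is required for mg/L to give
mg; the equation otherwise keeps the AF and ABS factors of the source
formulation (the conventional USEPA water-dermal form, which drops both, is
available via `conventional=True`). ADI units are mg/kg/**day** throughout:
AT is in days and with the defaults EF·ED/AT = 365·55/20075 = 1 exactly,
which the tests use as a wiring guard.

Default parameters (editable in `defaults.yaml`): IngRs 100 mg/day, IngRw
2 L/day, InhR 20 m³/day, EF 365 day/year, ED 55 year, BW 70 kg, AT = ED·365
day, PEF 1.36×10⁹ m³/kg, SA 5700 cm², AF 0.07 mg/(cm²·day), ABS 0.001,
ET 0.58 h/event. These describe a lifelong-resident adult; no child receptor
or food-chain pathway is modelled.

## Risk characterisation

- **THQ** = ADI/RfD per pathway, with pathway-specific reference doses
  (ingestion, inhalation and dermal RfDs differ per metal).
- **HI** = ΣTHQ over the assessed pathways, computed with exact (`fsum`)
  summation; HI ≥ 1 flags potential non-carcinogenic effects.
- **ILCR** = ADI·SF for the carcinogen set (default Pb, Cr, Cd, As). The
  *reported* ILCR is the ingestion-pathway value, because ingestion dominates
  the dose by 2–4 orders of magnitude and the reference results follow
  exactly that product; `ilcr_mode="sum"` reports the sum over assessed
  pathways instead.
- A missing RfD, SF or KP always produces an explicit not-assessed state
  (`None`), never a substituted zero — metals such as Mg and Ag carry no
  toxicity constants and their rows stay blank.

ILCR values are banded into seven Delphi risk levels (I: < 10⁻⁶ … VII:
≥ 10⁻³), again as half-open intervals, and flagged against the acceptable
range: below 10⁻⁶ no risk, within [10⁻⁶, 10⁻⁴] acceptable, above 10⁻⁴ high.
Where narrative grade labels in the reference results conflict with the
stated band table, the band table governs.

## Monte Carlo simulation

The probabilistic stage re-evaluates the water-ingestion ILCR
Cw·IngRw·EF·ED·SF/(BW·AT) per trial with inputs drawn independently from
configurable distributions. Supported kinds: point, uniform, triangular,
positive-truncated normal, and lognormal parameterised by its target
arithmetic mean and SD via method of moments (σ² = ln(1 + (sd/mean)²),
μ = ln mean − σ²/2). Defaults: lognormal concentrations moment-matched to the
observed well-water mean/SD; truncated-normal body weight (mean 70 kg, sd
10 kg, support > 0); point masses for IngRw, EF, ED, AT and SF. The original
analysis was run in a commercial spreadsheet add-in whose distribution
choices are unpublished, so its percentile table is treated as a
plausibility check, not a reproduction target; with these defaults the
package's P5/mean/P95 land within a few tens of percent of it.

Numerical contracts, all under test:

- n_trials defaults to 10,000; the seed is a required argument with no
  hidden default, and identical (config, seed) gives bit-identical results.
- Percentiles are empirical with linear interpolation between order
  statistics.
- Point-mass inputs collapse every draw to the deterministic ILCR (relative
  1e−12); scaling the concentration distribution by k scales draws, mean and
  percentiles by exactly k; the MC mean converges to the analytic mean
  (product of input means over point denominators) within 3 standard errors.
- Sensitivity is the Spearman rank correlation of each stored input with the
  ILCR draws, ranked by magnitude with sign preserved (body weight, in the
  denominator, comes out negative); inputs that did not vary are reported as
  0 with a constant flag. No Sobol indices and no input correlation
  structure are modelled.

## Synthetic data generator

The generator exists so the full pipeline is exercisable and testable with
no external data. Per metal, medium and group it draws lognormal samples
moment-matched to the configured mean/SD (defaults transcribed from the
study's summary tables: 26 site-soil, 5 control-soil, 5 site-well and 3
control-well samples); silver in water is generated as all-non-detect.
Lognormal is the minimal-assumption choice for positive, right-skewed
concentration data when only a mean and SD are reported. Two control-group
SDs are plausible placeholders marked `synthetic: true` in `defaults.yaml`
(one garbled in the source, two printed as 0.00 — a zero SD cannot be
moment-matched and is treated as a config error for n > 1).

Depth profiles interpolate geometrically from a surface value at 0 cm to a
plateau value at 50 cm (strictly decreasing whenever plateau < surface,
exactly flat below), with multiplicative lognormal noise of configurable CV
(default 5 %, mean 1 so expectation is preserved); zero noise reproduces the
deterministic shape exactly.

What the generator does **not** emulate: spatial structure (sample positions,
kriging), inter-metal correlation within a sample, measurement censoring
beyond the all-or-nothing Ag case, and seasonal variation. Tests passing on
synthetic data therefore demonstrate the correctness of the computational
pipeline and its statistical contracts — not field validity of any single
site's numbers.

## Problem sizes and tolerances

Parameter-recovery and Monte Carlo convergence tests use n = 10,000 draws
with 3-standard-error acceptance; the deterministic golden-value tests
assert printed-table cells to within half a unit in the last printed digit
(one cell, the Zn soil dermal minimum, sits exactly on that half-ulp
boundary, and one reference HI sum is printed truncated rather than rounded
and is asserted against its exact sum). The dose-equation oracle check uses
1,000 random parameter draws at relative tolerance 1e−12. Tabular output
rounds half-away-from-zero at 3 significant figures in the `d.ddE-n` style,
switching to fixed notation when the base-10 exponent lies in [−2, 2]; CSV
outputs keep full precision.

## Known limitations

- Single adult receptor; no child, no food-chain intake, no dermal
  inhalation-phase chemistry.
- Several cells of the reference result tables are internally inconsistent
  (mean-row doses vs printed mean concentrations, a subset of enrichment
  factors ~10× off the site/control quotient, the water-dermal dose column,
  and a grand-total HI); the package computes from its inputs and documents
  the bands/equations it follows rather than emulating those cells.
- Guideline screening uses the mean concentration only; no upper-bound or
  per-sample exceedance statistics.
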