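# Methods

## The measurement being modelled

A soil sample sits in a closed headspace vial with a reservoir of
isotopically enriched water (²H₂O or H₂¹⁸O) that never touches the soil.
Over a 48 h incubation the reservoir equilibrates with soil water through
the vapor phase; organisms assimilating water hydrogen into fatty acids, or
water oxygen into DNA, acquire the label in proportion to how much of each
pool they synthesized. The package turns three raw observations — compound
δ²H values from GC-IRMS, bulk-DNA ¹⁸O atom percent, and headspace CO₂ —
into growth, storage synthesis, CUE and turnover.

## Calibration

Raw δ-values measured against the working reference gas are normalized to
the VSMOW scale by ordinary least squares of known on measured δ across
bracketing standards. The instrument drifts over a sequence; the functional
form of that drift is not constrained by the assay, so the package uses the
minimal model — linear in run position — estimated jointly with the line
whenever a standard compound appears at two or more positions, and fixed at
zero otherwise. δ → atom percent uses the two-isotope relation
`R = (δ/1000 + 1)·R_std`, `at% = 100·R/(1+R)` with VSMOW ratios
`R(²H/¹H) = 1.5576e-4` and `R(¹⁸O/¹⁶O) = 2.0052e-3`; the third oxygen
isotope is ignored, which is adequate at tracer enrichments of several
atom percent. Fatty-acid carbon is quantified against the 19:0 internal
standard, `FA C_i = (area_i/area_IS)·C_IS/soil dry mass`; an optional
per-compound response-factor table exists but defaults to none, and no
correction is applied for the methyl group added by transesterification
(a flag exists, default off). H3-factor and memory-effect corrections are
assumed handled upstream by the instrument software.

## Equilibration kinetics

Soil-water enrichment over time follows
`X(t) = X_end + (X_start − X_end)·e^(−bt)` with a soil-specific rate
constant `b` (h⁻¹). The curve is fitted by bounded nonlinear least squares
(`scipy.optimize.curve_fit`, `b ∈ [1e−6, 1e3] h⁻¹`, sum-of-squares
tolerances 1e−14) with `b` initialized from log-linearized residuals. The
same generic form fits either a decaying source series or the rising soil
series; soil enrichment is derived from the source reservoir's label loss by
exact two-pool conservation,
`soil at%(t) = soil_nat + (m_source/m_soil water)·(source at%(0) − source at%(t))`,
and the soil-rise series is the canonical input. A series with no spread is
returned as a degenerate flat fit rather than an error, since it is the
correct limit of zero exchange.

The quantity the flux equations need is the enrichment organisms experienced
*on average*, so the denominator is the closed-form time average of the
fitted curve over the incubation window; an adaptive-quadrature cross-check
agrees to 1e−9 relative (property-tested over random parameter draws).
Replicate series within a treatment are fitted individually and their
averages averaged; that treatment mean applies to every sample of the
treatment. Where a phase × treatment cell has no measured series — in the
field campaign only the peak-drought phase was sampled for curves — the
lookup falls back to the matching non-drought cell, then to the peak-drought
cell, with a logged notice.

## Tracer fluxes

Both tracers reduce to one kernel: produced = pool ×
(at%_labelled − at%_natural)/denominator. For fatty acids the denominator is
`a_w · at%_soil water`, where `a_w` is the water-hydrogen assimilation
constant — the fraction of fatty-acid hydrogen drawn from ambient water
including net fractionation, 0.71 for heterotrophic communities (surveys
place it between ~0.1 and ~1; every lipid growth estimate scales exactly as
1/a_w, and this sensitivity is property-tested). For DNA the denominator is
the soil-water at% alone — no assimilation constant is in use for DNA — and
the produced oxygen converts to DNA mass through the mean oxygen content of
DNA, 31.21% by mass.

Excess enrichments can be negative at near-zero growth because IRMS noise
(~4‰ on δ²H) dwarfs the signal; by default these clamp to zero with a
per-record flag and a reported count rather than propagating negative
production. `FA C` in the flux equation is the mean of the labelled and
natural-abundance samples' amounts. Pairing with the natural-abundance vial
is part of the input contract: every fatty-acid record carries both the
labelled and the paired natural-abundance value (from the same plot's
unlabelled incubation), so the pairing decision is made where the plot
layout is known rather than guessed downstream.

Community growth converts the produced fraction of the measured pool (PLFA
or DNA) into biomass terms:
`Growth = fraction_new · Microbial BM C / time`, in ng C g⁻¹ dry soil h⁻¹
with biomass from chloroform fumigation in µg C g⁻¹. The DNA-based growth
divides by incubation time exactly as the lipid-based growth does, making
both hourly rates; this is required for CUE to combine growth with hourly
respiration, and turnover in days follows as the reciprocal of the daily
mass-specific rate. Group-specific mass-specific rates divide each group's
summed production by its summed FA C and the incubation time; a group with
zero FA C is omitted with a notice, never reported as zero. Fungi:bacteria
ratios use fungi over (gram-positive sum + gram-negative), where the
gram-positive sum includes actinobacteria via a registry flag; the AMF
marker 16:1ω5 and the general markers enter neither side. Storage investment
is newly produced NLFA as a percentage of newly produced PLFA, per group,
computed only over markers present in both fractions.

## Respiration and physiology

Headspace ppm is treated as µmol CO₂ per mol of gas at vial pressure:
`mol = P·V·Δppm·1e−6/(R·T)`, converted to ng C (12.011 g mol⁻¹) per g dry
soil per hour. The default free volume is 25.8 mL (27 mL vial minus the
1.2 mL inner vial; the soil's own displacement is configurable since it is
setup-specific). A CO₂ decrease beyond 5 ppm flags a suspected leak but
still returns the rate, leaving the decision to the analyst. CUE pairs each
sample's growth with the respiration of the same labelled vial over the same
window. Turnover `T = BM C/(Growth·24)` is reported raw and rounded to whole
days; treatment-level turnover uses treatment-mean biomass over
treatment-mean daily production (the mean of per-sample turnovers is emitted
alongside, since the two differ under Jensen's inequality).

## Treatment summaries

Drought contrasts compare each drought cell with its matching non-drought
climate (ambient↔drought, future↔future+drought) as percent reduction and
fold change, plus a pooled value defined as the mean of the two
climate-specific contrasts; both per-climate and pooled rows are emitted so
either convention is reproducible. The label-toxicity check is a two-sided
paired t-test of labelled vs natural-abundance respiration
(`t = mean(d)/(sd(d)/√n)`, df = n−1), cross-checked against
`scipy.stats.ttest_rel`. Mixed-effects models, PCA and PERMANOVA are
deliberately out of scope; the pipeline exports tidy per-sample tables
shaped for external fitting.

## Synthetic data: what it emulates and what it does not

The generator forward-simulates the full factorial campaign (ambient,
drought, future climate, future + drought; peak-drought and recovery phases;
four plots per treatment; 48 h at 20/23 °C) by inverting every pipeline
equation exactly, so noise-free datasets are recovered to numerical
precision at every stage — the central correctness argument of the package.
Default ground truth encodes the qualitative pattern the assay is designed
to resolve: ambient communities turning over in ~96 days, drought halving
gram-positive and gram-negative growth while fungal (and AMF) rates are
unchanged and actinobacteria decline least, fungal NLFA:PLFA investment
rising from 22% to 228–305%, respiration falling roughly in proportion to
growth (CUE unchanged by drought), and soil water equilibrating toward
13–21 at% plateaus at b ≈ 0.1–0.25 h⁻¹ sampled at 0/3/6/16/48 h.

Noise enters where the instruments see it: δ-space for ²H (sd 4‰, the
bracketing-standard reproducibility), at% for bulk-DNA ¹⁸O (sd 5e−4),
ppm for CO₂ (sd 3). A log-normal plot multiplier (sd 0.12, mean 1) is shared
by all rates of a sample, so the two tracers and respiration stay internally
consistent per sample. Not emulated: real marker-composition shifts between
treatments, extraction/derivatization efficiency differences, chromatographic
co-elution, NLFA necromass persistence, and rewetting (Birch-effect) pulses —
so passing recovery tests demonstrates the calculus and its noise
propagation, not field realism of any particular number.

## Numerical and design choices

- Optimizer bounds keep `b` positive; a plateau-only series short-circuits
  to the degenerate flat fit instead of hitting the bound.
- The closed-form time average switches to its series limit below
  `bW < 1e−12` and to `1/(bW)` above the exp-underflow threshold.
- Marker names normalize spacing, case, ω/w and cis/trans spellings; the
  registry is a CSV shipped with the package so users can extend it, and an
  unknown marker degrades to the general group with a logged notice rather
  than an error.
- Validation is total at the I/O boundary: missing columns, unparseable
  numerics (reported with line numbers) and unknown enum labels are typed
  errors; no silent NaN propagates.
- Problem sizes in the test suite: the Monte-Carlo recovery check runs 200
  seeded campaigns restricted to the peak-drought phase (16 samples each),
  and the integral cross-check draws 1000 parameter sets — sizes chosen to
  make sampling statements (≥95% of seeds) meaningful while keeping the
  suite fast.

## Known limitations

- `a_w` is a single community-wide constant; taxon-specific assimilation
  would change group contrasts, not just scale them.
- NLFA production is not corrected for storage-pool turnover (degradation
  rates in soil are unknown), so storage investment may be underestimated.
- Bulk-DNA ¹⁸O gives community rates only; no density-gradient,
  taxon-resolved qSIP is attempted.
- The equilibration model neglects evaporation/condensation fractionation
  over the 48 h window, consistent with the mass-balance treatment.
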