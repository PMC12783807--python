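# Methods

## Model and procedure

The package assesses multi-element eutrophication potential at river
mouths from three routinely monitored quantities: dissolved inorganic
nitrogen (DIN = nitrate(+nitrite) + ammonium), total phosphorus and
dissolved silica. The reference point is the Redfield molar ratio
N:P:Si = 16:1:20, the stoichiometry at which siliceous phytoplankton can
in principle use all three elements jointly. Three derived views share
this single reference:

1. **Ternary composition.** Each molar triplet is scaled by (1/16, 1,
   1/20) and closed to 100%, so 16:1:20 sits at the triangle centre. An
   element under 20% of the scaled total is *depleted* — a stoichiometric
   statement about relative shortage, deliberately weaker than
   demonstrated growth limitation. The 20% cut-off is a convention;
   exactly 20% counts as not depleted (the rule is strict "less than"),
   and any threshold in (0, 33.3) is accepted — above 100/3 a triple
   depletion would be possible, which the zone vocabulary excludes.

2. **Trophic state of the depleted nutrient.** A single Carlson-style
   index is reported, never a composite: TSI(TotP) = 4.15 + 14.42·ln(TotP
   µg l⁻¹) when molar N:P > 16 (P relatively short), else TSI(DIN) =
   54.45 + 14.43·ln(DIN mg l⁻¹). N:P exactly 16 takes the P branch — the
   tie is measure-zero but must be deterministic, and the published
   branch labels attach "> 16" to the P equation. Class bins are
   half-open, closed on the left of the higher class: TSI = 30 is
   oligotrophic, TSI = 60 hypereutrophic. A zero concentration yields
   −∞, reported as ultra-oligotrophic and flagged by the −∞ value itself.

3. **ICEP and critical concentrations.** ICEP converts the excess of N or
   P flux over what the Si flux could balance into potential carbon
   fixation by non-siliceous taxa (kg C km⁻² d⁻¹), using the integer
   molar masses 14/31/28 and the factor 106·12. Because flux =
   concentration × runoff, setting ICEP = 0 gives runoff-free critical
   concentrations DIN₀ = (14·16)/(28·20)·Si = 0.4·Si and TotP₀ =
   31/(28·20)·Si ≈ 0.055·Si, and exceedance ratios D = measured/critical
   with sign(ICEP) = sign(D − 1) identically in runoff. The package
   computes ICEP only where runoff is supplied; critical concentrations
   and exceedances always.

**Units discipline.** All stoichiometric equations use the integer molar
masses 14, 31, 28 — the printed factors 0.4 and 0.055 follow from them
exactly. The single exception is the SiO₂→Si conversion (28.08/60.08),
where the precise masses are the stated rule. Mass→molar conversion
happens once at the module boundary (`units.to_molar`); everything
downstream is molar until CSV output.

## Ingest and quality control

Raw CSVs may report nitrate+nitrite or nitrate alone, plus ammonium; DIN
is the sum of whatever inorganic-N species are present, and is missing
only when all are — monitoring programmes legitimately differ in which
fractions they measure, so a single-species DIN is a definition, not an
error. Si comes from an `si` column or from SiO₂ by molar-mass ratio.
Below-detection rows (marked by a `detection_limit_<analyte>` value) are
replaced by half the limit by default (`as_reported` keeps the value);
duplicate site-date rows are averaged before anything else (order-free);
an optional depth column is filtered at < 1 m. A site is retained only if
every calendar year of the study window (default 2017–2024) has at least
six samples with DIN, TotP and Si jointly usable; the three analytes are
required jointly because every downstream metric needs the full triplet.

## Aggregation ladder

All metrics are computed per sample first and only then averaged —
never by re-entering averaged concentrations into the equations, except
for the site-level classifications (zone, TSI basis and value), which are
assigned from the aggregated percentages/concentrations because a site
is given one class, not a distribution. Annual value = mean of the
year's samples; overall = mean of annual means (years weigh equally
regardless of sampling effort); calendar-month value = mean over years
of the within-year-month means (a pooled alternative is available via
`within_year_first=False`). The minimum monthly Redfield Si% flags
potential seasonal depletion; ties go to the earliest calendar month.
Seasons: Mar–May spring, Jun–Aug summer, Sep–Nov autumn, Dec–Feb winter.

## Synthetic data generator

The generator emulates a Nordic-style monthly monitoring network: site
medians of DIN and TotP fall log-linearly with latitude (defaults
2000→50 and 120→5 µg l⁻¹ over 55–70°N — southern agricultural
catchments rich, northern sub-Arctic ones poor), Si is
latitude-independent (median 2700 µg l⁻¹, between-site geometric SD 1.3),
and Si carries a seasonal factor 1 − depth·cos(2π(m − trough)/12)
(default trough May, depth 0.30) whose annual mean is exactly 1.

Per-sample noise is ONE lognormal, median-preserving factor with CV 0.4
applied to all analytes of a sample. This emulates flow-driven
dilution/concentration — the dominant source of variability in river
chemistry, and common to all solutes of a water sample. It deliberately
does **not** emulate independent analytical error per analyte:
consequently per-sample Redfield percentages are exactly scale-invariant
to the noise, and recovery tests of composition-derived quantities probe
the aggregation machinery and seasonal structure rather than a
measurement-error model. Concentration-scale quantities (TSI, exceedance
ratios) do feel the noise. Passing recovery tests therefore show the
pipeline is faithful under realistic hydrological variability; they say
nothing about robustness to large uncorrelated laboratory error, which
real data add on top.

The truth table is computed analytically from the site medians (zone,
TSI basis and class, minimum-Si month from the seasonal factor), not
from the simulated samples, so recovery has an unambiguous target. The
small residual zone-recovery error (~2% of sites at noise CV 0.2) is a
real property of the procedure: monthly aggregation averages a
*nonlinear* function of the seasonal factor, so a site whose median
composition sits within a few tenths of a percentage point of the 20%
boundary can be classified differently from its median — not a bug, and
left visible.

`make_redfield_site` inverts the equations for tests: it picks an
archetype composition inside a requested zone, converts it to a molar
ray (compositions are scale-invariant) and scales the ray so the
depleted-nutrient TSI lands mid-class; the result is verified against
the forward computations before being returned.

## Numerical choices and degenerate inputs

* All-zero molar triplets are rejected (composition undefined); in
  vectorised calls they propagate as NaN and are excluded downstream.
* Zero Si gives zero critical concentrations; the exceedance of a
  positive measurement is then +∞ (unbounded risk), 0/0 is NaN.
* Floating outputs are written at 6 significant digits; internal
  computation is double precision throughout.
* A run manifest (SHA-256 config hash, row counts, per-site drop
  reasons) accompanies every output so a table is traceable to exactly
  one configuration.

## Problem sizes

The default simulated network is 50 sites × 8 years × 12 monthly
samples (4 800 records), comfortably representative of the ~20–90-site
national networks the generator emulates; recovery checks use the same
size with noise CV 0.2. The randomized identity checks use 1 000 draws.

## Known limitations

* No hydrological realism: no flow time series, hysteresis, reservoir or
  lake-retention effects; runoff is a per-site constant used only for
  ICEP.
* No trend analysis across years, no flow-weighted means (arithmetic
  means only), and no salinity-scaled Redfield Si term — though the Si
  term is a single configuration knob (16…40) for sensitivity work.
* Depletion is stoichiometric, not demonstrated limitation; the 20%
  zones and the 16:1:20 reference are conventions chosen for
  comparability with SDG 14.1.1a-style reporting, not fitted quantities.
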