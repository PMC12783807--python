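# npsi — river-mouth N:P:Si stoichiometry assessment

`npsi` turns monthly river-mouth water-chemistry records (dissolved
inorganic nitrogen, total phosphorus and dissolved silica) into a
multi-element eutrophication assessment. It is written for aquatic
biogeochemists and monitoring programmes that want to go beyond
single-nutrient targets: the balance of N and P against available Si
decides whether diatoms or potentially harmful non-siliceous taxa can
dominate coastal phytoplankton.

## What it computes

With molar concentrations DIN, TotP, Si (µmol l⁻¹) and the Redfield
reference ratio N:P:Si = 16:1:20, each sample gets:

* **Redfield ternary coordinates**

  Redfield_N% = 100 · (DIN/16) / (DIN/16 + TotP + Si/20), and likewise for
  P (TotP term) and Si (Si/20 term). A 16:1:20 sample plots at the centre
  (33.3, 33.3, 33.3). Any component below 20% is *depleted*; the depletion
  zone is the set of depleted elements (N, P, Si, NP, NSi, PSi) or
  *balanced*.

* **Trophic state index of the depleted nutrient** (Carlson-style)

  TSI(TotP) = 4.15 + 14.42·ln(TotP µg l⁻¹) when molar N:P > 16,
  TSI(DIN) = 54.45 + 14.43·ln(DIN mg l⁻¹) otherwise; classes
  ultra-oligotrophic (<30) through hypereutrophic (≥60).

* **ICEP and critical concentrations**

  ICEP(P) = [PFlx/31 − SiFlx/(28·20)]·106·12 (kg C km⁻² d⁻¹), with an N
  analogue using 14·16; ICEP = 0 is the balanced threshold. Rearranged at
  zero, critical concentrations need no flux data at all:
  DIN₀ = 0.4·Si and TotP₀ ≈ 0.055·Si (µg l⁻¹), and exceedance ratios
  D = measured/critical, where D > 1 is exactly equivalent to ICEP > 0.

Metrics are computed per sample and aggregated sample → monthly/annual →
overall (mean of annual means), with the minimum monthly Redfield Si% and
its season flagging potential seasonal Si depletion. A synthetic-data
module generates monitoring-like networks (north–south N/P gradient,
latitude-independent Si, spring Si trough) with an analytic truth table
for parameter-recovery testing.

## Worked example

```sh
python analysis/01_simulate.py   # synthetic 50-site network, 2017-2024
python analysis/02_assess.py     # QC -> per-sample metrics -> site summaries
python analysis/03_figures.py    # ternary / TSI / seasonal / exceedance plots
```

The assessment step prints, for the default simulation (seed 42):

```
retained 50 sites (0 dropped by QC)

depletion zones (overall averages):
zone
NP_depleted    25
P_depleted     19
balanced        6

season of the minimum monthly Redfield Si %:
min_si_season
spring    50

sites with seasonal Si depletion (min monthly Si% < 20): 2
sites with DIN exceedance (D_DIN > 1): 7
sites with TotP exceedance (D_TotP > 1): 0

recovery vs truth: zones 96%, min-Si month 100%
```

Most sites are P- or jointly NP-depleted relative to Si (ample silica for
diatom growth), the Si minimum falls in spring at every site (the
simulated drawdown troughs in May), TotP almost never exceeds its
critical concentration while DIN does at the nutrient-richest southern
sites, and the pipeline recovers 48/50 true depletion zones and all
minimum-Si months from noisy samples. `results/site_summary.csv` holds
one row per site (composition, zone, TSI, critical concentrations,
exceedances, ICEP); `results/monthly_metrics.csv` the per-calendar-month
values.

The same pipeline runs on real monitoring CSVs via the CLI:

```sh
npsi assess --samples samples.csv --sites sites.csv --config run.yaml --out results/
```

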