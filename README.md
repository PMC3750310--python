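# cadexpo

Point and probabilistic assessment of dietary and environmental cadmium
exposure for a non-occupationally exposed adult population, with
tolerable-intake risk characterization, contribution-to-variance sensitivity
analysis, biomonitoring statistics, and a calibrated synthetic survey cohort.

The package re-implements, as a reusable analysis pipeline, the exposure
assessment conducted on a 2008 cross-sectional survey of 207 Shanghai
residents over 40: a food frequency questionnaire reduced to a 14-category
food summary table (per-food cadmium concentration and daily intake, each
summarized by mean/std/median/P90), combined with tobacco and drinking-water
cadmium to estimate total daily exposure, compared against the provisional
tolerable daily intake (PTDI), and checked against urinary and blood cadmium
(UCd, BCd) measured in the same participants.

## The model

**Point estimation.** With concentration c_f (mg/kg ≡ μg/g) and intake q_f
(g/day), per-food exposure at four summary levels is

    mean:        E_f = c̄_f · q̄_f
    median:      E_f = med(c_f) · med(q_f)
    P90:         E_f = c̄_f · P90(q_f)
    extreme P90: E_f = P90(c_f) · P90(q_f)

Total exposure adds a water term (half-LOD concentration × 1.2 L/day) and a
smoking term (tobacco Cd per gram × grams per cigarette × cigarettes/day):
E_total = Σ_f E_f + E_water + E_smoke, characterized as E_total / PTDI × 100%
with PTDI = PTMI × BW / 30.3 days = 25 × 60 / 30.3 ≈ 49.5 μg/day.

**Probabilistic estimation.** Each input is a lognormal fit by the method of
moments to the summary table (σ² = ln(1 + (s/m)²), μ = ln m − σ²/2); the
smoking term is Bernoulli(prevalence) × lognormal(cigarettes/day) × tobacco
content. A seeded Monte Carlo engine (default n = 100,000) propagates the
inputs through the total-exposure equation and reports the empirical
distribution and the below-PTDI probability P(E_total ≤ PTDI).

**Sensitivity.** Contribution to variance of input i is the normalized
squared Spearman rank correlation r_i²/Σ_j r_j² × 100 between the input's
draws and the simulated output — the convention of spreadsheet risk tools.

**Biomonitoring.** Below-LOD measurements are substituted by LOD/2; group
contrasts use the two-sided Mann–Whitney U test; external–internal dose
agreement uses Pearson (or Spearman) correlation.

## Worked example

```sh
python analysis/01_point_estimation.py
```

prints, from the bundled food summary table:

```
total exposure as % of PTDI by level:
          mean:   33.8%
        median:    6.7%
           p90:   74.3%
   extreme_p90:  223.5%
```

i.e. the mean total daily exposure (16.7 μg/day = 12.8 dietary + 3.9 smoking
+ 0.03 water) is about one third of the 49.5 μg/day tolerable intake, and
only the extreme upper bound (90th-percentile concentration × 90th-percentile
intake for every food simultaneously) exceeds it. The remaining drivers
continue the analysis:

```sh
python analysis/02_probabilistic_exposure.py   # per-stratum Monte Carlo + risk
python analysis/03_sensitivity_analysis.py     # contribution-to-variance table
python analysis/04_cohort_biomonitoring.py     # synthetic cohort + UCd/BCd stats
```

`02` reports, per stratum, the simulated exposure summary and below-PTDI
probability (≈0.95 total, ≈0.90 smokers, ≈0.98 non-smokers with the default
seed); `03` ranks inputs by variance contribution (tobacco consumption ≈36%,
vegetable cadmium ≈26%, rice cadmium ≈23%); `04` generates a 207-person
synthetic cohort and recovers the published internal-dose structure (smokers'
BCd ≈ 1.0 vs non-smokers' ≈ 0.3 μg/L, p ≪ 0.001; corr(exposure, BCd) ≈ 0.5;
corr(age, UCd) ≈ 0.15 on average over seeds).

The same stages are available as a CLI (`cadexpo point-estimate|simulate|
sensitivity|synth-cohort|biostats|run`); `cadexpo run --out-dir out/` chains
them and writes a reproducibility manifest.

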