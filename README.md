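# lizardgrowth

Growth-ecology analysis for capture–recapture studies of small lizards.

Tropical anoles are short-lived, fast-growing lizards: hatchlings emerge in
the autumn wet season at ~22 mm snout–vent length (SVL), reach sexual
maturity within their first year, reproduce once, and die. Field studies
follow marked individuals over monthly capture sessions and measure growth
as the SVL increment between captures. This package turns such
capture–recapture records into a full growth analysis:

1. **Growth intervals** — per individual, the growth rate
   `GR = (SVL₂ − SVL₁) / days` between the first and last capture, retained
   for recapture spans of 30–100 days, with age class (sex-specific SVL
   thresholds), wet/dry season (wet = July–November) and year attached.
2. **Model fitting and selection** — nonlinear least squares of three
   classical growth-rate laws against reference length *L*:

   | family | differential form | integrated solution |
   |---|---|---|
   | von Bertalanffy | GR = A₁r(1 − L/A₁) | L(t) = A₁(1 − be^(−rt)) |
   | logistic-by-length | GR = Lr(1 − L/A₁) | L(t) = A₁/(1 + be^(−rt)) |
   | logistic-by-weight | GR = (rL/3)(1 − L³/A₁³) | L(t) = [A₁³/(1 + be^(−rt))]^(1/3) |

   with asymptotic size A₁ (mm), characteristic growth parameter r (day⁻¹),
   and shape constant b anchoring the curve at hatchling size L₀. The best
   family per sex is the one with the lowest mean squared residual
   (MSR = SSres/(n−2)); R² breaks ties.
3. **Life history** — growth curves anchored at L₀, age at sexual maturity
   by closed-form inversion of the curve at the maturity SVL (35 mm males,
   37 mm females), per sex × age class × season × year growth summaries,
   fixed-effects ANOVA contrasts, and Pearson correlations of monthly mean
   growth with prey abundance, prey-category richness, temperature and
   precipitation.
4. **Synthetic data** — an individual-based generator that emulates the
   field design (two semelparous autumn cohorts, ~700 marked individuals
   over 24 monthly sessions, measurement error, seasonal prey/climate
   series), so every stage is testable end to end.

A two-year prey-availability sweep-net survey from the Chamela tropical dry
forest (Jalisco, Mexico) is bundled as a reference dataset for the
prey-aggregation stage.

## Worked example

```python
from lizardgrowth import (SimConfig, simulate_capture_recapture, extract_intervals,
                          fit_all_families, compare_models, build_growth_curve,
                          age_at_maturity)

cfg = SimConfig(seed=42)                      # defaults emulate the field design
individuals, captures = simulate_capture_recapture(cfg)
intervals = extract_intervals(captures, window=(30, 100))
males = intervals[intervals.sex == "male"]
comp = compare_models(fit_all_families(males))
print(comp.best.summary())
curve = build_growth_curve(comp.best, l0=22.1)
print(f"age at maturity (35 mm): {age_at_maturity(curve, 35.0):.0f} days")
```

prints

```
Growth-rate model fit
==============================================
family:     logistic_by_length
n:          51
MSR:        0.000146039 (mm/day)^2
R^2:        0.3665
converged:  True
----------------------------------------------
A1 (mm):    47.4263 +/- 1.5639
r (1/day):  0.005145 +/- 0.000322
==============================================
age at maturity (35 mm): 228 days
```

The simulated males were generated under a logistic-by-length law with
A₁ = 46.46 mm and r = 0.0053 day⁻¹; the selection rule recovers the
generating family and the estimates land within a standard error of the
generating values. The maturity age is the closed-form inversion of the
fitted curve at 35 mm.

The same stages are available from the shell:

```bash
lizardgrowth simulate --seed 42 --out sim/
lizardgrowth intervals sim/captures.csv --out intervals.csv
lizardgrowth fit --captures sim/captures.csv --out results/
lizardgrowth maturity --family logistic_by_length --a1 46.46 --r 0.0053 --l0 22.1 --svl 35
lizardgrowth full --seed 42 --out results/
```

Exit codes distinguish schema (2), convergence (3) and series-alignment (4)
failures.

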