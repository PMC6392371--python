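# Methods

## Growth increments from capture–recapture data

The unit of analysis is the per-individual growth rate
`GR = (SVL₂ − SVL₁)/Δdays` (mm/day). By default each marked individual
contributes **one** interval, from its first to its last capture, kept only
when the elapsed time lies in a 30–100-day window; intermediate captures of
multi-recapture animals are not used. This keeps intervals statistically
independent (one datum per animal) and matches group sample sizes that sum
to the number of marked animals rather than the number of capture events. A
per-consecutive-pair mode exists behind a flag for sensitivity analyses.

Each interval carries a reference length `L_ref` used as the model
predictor. The default is the midpoint `(SVL₁+SVL₂)/2`: the measured
increment estimates the growth rate around the centre of the interval, and
for a rate that is approximately linear in L over a 1–3-month span the
midpoint makes the pairing first-order unbiased. `L_ref = SVL₁` is available
as an option.

Age class at the interval's first capture uses sex-specific SVL thresholds
(juvenile males 25–31 mm, adults > 32 mm; juvenile females 25–34 mm, adults
> 35 mm). The published class bounds leave gaps (31–32 mm males, 34–35 mm
females); any length not strictly above the adult threshold classifies as
juvenile, which also covers hatchling-sized animals below the juvenile
lower bound. Season is calendrical: wet = July–November (5 months), dry =
December–June (7 months), assigned at the first capture. Negative intervals
(apparent shrinkage, i.e. measurement error) are retained but flagged; an
exclusion switch exists.

## The three growth laws

All three families express the growth rate as a function of current length
with two free parameters, the asymptotic SVL `A₁` (mm) and the
characteristic growth parameter `r` (day⁻¹); rates are per day because
recapture spans are measured in days.

- **von Bertalanffy** `GR = A₁r(1 − L/A₁)`: rate declines linearly from
  `A₁r` at L = 0; no interior maximum, so "fastest growth" occurs at the
  smallest observable length.
- **logistic-by-length** `GR = Lr(1 − L/A₁)`: sigmoid growth, maximum rate
  at `L = A₁/2`.
- **logistic-by-weight** `GR = (rL/3)(1 − L³/A₁³)`: the logistic law in
  mass transported to length under an isometric mass ∝ L³ assumption (it
  remains an equation in length); maximum rate at `L = A₁·4^(−1/3) ≈
  0.63·A₁`, always later than the logistic-by-length peak.

The integrated solutions (see README table) are evaluated in closed form
only; numerical ODE integration appears solely as an independent oracle in
the tests. The shape constant `b` (`1 − L₀/A₁`, `A₁/L₀ − 1`,
`A₁³/L₀³ − 1` respectively) anchors each solution at the mean hatchling
size `L₀` at age 0, and inversion to `t(L)` is likewise closed-form.

## Fitting and model selection

Parameters minimise the sum of squared rate residuals
`Σ(GRᵢ − GR(L_ref,ᵢ; A₁, r))²`, pooling juveniles and adults within a sex.
Each family is linear in a transformed parameterisation (e.g. von
Bertalanffy: `GR = rA₁ − rL`), so exact linear least-squares estimates are
available in closed form; they seed a trust-region-reflective optimiser in
the `(A₁, r)` parameterisation (bounds `A₁, r > 0`, fallback start
`A₁ = 1.1·max L_ref`, `r = 0.005`; tolerances 10⁻¹² on cost, parameters and
gradient; at most 10,000 evaluations). Standard errors come from the
curvature of the least-squares surface, `cov = MSR·(JᵀJ)⁻¹`. Convergence is
reported honestly on the result object rather than raised.

Goodness of fit: `MSR = SSres/(n − 2)` — the criterion's denominator is not
standard in the field literature, and residual degrees of freedom are used
here for unbiasedness; the selection is rank-invariant to the choice of
denominator because all families have two parameters. `R² = 1 − SSres/SStot`
about the observed mean. Selection takes the lowest MSR; an exact MSR tie
goes to the higher R², then to a fixed family order (von Bertalanffy,
logistic-by-length, logistic-by-weight). When MSR and R² disagree about the
best family, MSR wins and the conflict is recorded on the comparison
object. AIC-style criteria are deliberately not offered as the selection
rule.

The published fit table this machinery mirrors reports MSR ≈ 0.31 (mm/day)²
against growth rates of order 0.02–0.10 mm/day — three orders of magnitude
larger than the residual variance such rates can produce. The original MSR
scale or normalisation is evidently different from its stated units; no
rescaling is applied here, and MSR values from this package are on the
honest (mm/day)² scale.

## Growth curves and age at maturity

The selected fit per sex plus `L₀ = 22.1 mm` (field mean of hatchlings,
SD 1.5 mm, range 19–24 mm) defines the growth curve; the age at sexual
maturity is `t(SVL_mat)` by closed-form inversion, with `SVL_mat = 35 mm`
(males) and `37 mm` (females), reported in days and months (÷30).

**Documented discrepancy.** With the published per-sex estimates
(males logistic-by-length A₁ = 46.46, r = 0.0053; females von Bertalanffy
A₁ = 52.81, r = 0.0017) and L₀ = 22.1, inversion gives **229 days** for
males at 35 mm and **391 days** for females at 37 mm. The source study
reports 210 and 270 days for the same sizes. Those ages are not obtainable
from the printed parameters by any of the three solutions; they may derive
from phenological timing (autumn hatching to the observed onset of breeding
the following spring/summer) or from unreported parameter values. The
package computes and reports the inversion; it does not force agreement.

## Group summaries, ANOVA, correlations

Group summaries report n, mean and standard error (`sd/√n`; singleton cells
report SE 0) of GR per sex × age class × season × year cell. ANOVA is
fixed-effects: the classical one-way F test for a single factor, an
additive linear model with type-I (sequential) sums of squares for several
factors (via statsmodels), with conventional degrees of freedom
`(k−1, n−k)`. The df pairs printed in the source study (e.g. `F₂,₆₉₈` for
two-level factors) cannot be reconstructed from any standard design; this
package reports conventional df and makes no attempt to match.

Growth–environment correlations are Pearson coefficients with two-sided
p-values, no multiple-testing correction. Monthly aggregation pairs the
mean GR of all intervals whose midpoint date falls in a calendar month with
that month's total prey count, prey-category richness (order × life stage
with positive totals; larvae and adults of Coleoptera, Hymenoptera and
Lepidoptera count separately — the only reading under which the survey's
published richness values 10/10/11/12 are reproduced), mean temperature and
total precipitation. Both a pooled two-year series and per-year series are
possible; the pipeline uses the pooled series by default.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study design, not the biology beyond it:

- **Population**: two semelparous cohorts hatching September–November of
  consecutive years; sex drawn with the observed 402:300 female:male ratio;
  `L₀ ~ N(22.1, 1.5)` truncated to 19–24 mm.
- **Growth**: deterministic per-sex curves with population-constant
  `(A₁, r)` (males logistic-by-length 46.46/0.0053, females von Bertalanffy
  52.81/0.0017). Individual heterogeneity enters only through L₀ and
  measurement error, matching the population-level fitting the analysis
  performs.
- **Observation**: 24 monthly mid-month sessions over two years; capture
  probability 0.20 per session; geometric survival 0.90 per month; Gaussian
  SVL measurement error (SD 0.5 mm). The population size default (1,115)
  makes the expected number of marked animals ≈ 702, the scale of the
  original study; a semelparous die-off option kills animals at the end of
  the wet season of their second year.
- **Environment**: monthly prey totals Poisson with seasonal means 68 (wet)
  and 12 (dry) per month — the seasonal contrast of the bundled survey —
  split multinomially over the survey's category pool with season-specific
  weights, so rare categories blink in and out and richness varies;
  temperature a small annual sine (mean 25 °C, amplitude 1.5 °C);
  precipitation gamma-distributed, concentrated in July–November.

For parameter-recovery experiments a direct interval generator draws
`L_ref ~ Uniform(L₀, 0.95·A₁)` and adds Gaussian rate noise (default SD
0.02 mm/day, chosen so fitted R² lands in the ≈ 0.2–0.4 range the field
data show). The within-individual growth variance of the real population is
unknown; this noise model is a construction, and passing recovery tests
demonstrates correctness of the estimation machinery under the stated
noise, not that the field data meet those assumptions. Real capture data
additionally contain size-dependent catchability, transients and
identification errors, none of which are modelled.

The von Bertalanffy asymptote estimator is a ratio of linear-model
coefficients and carries a small positive finite-sample bias
(≈ +0.2–0.5 mm at 300 intervals with rate noise SD 0.02); recovery is
assessed on Monte-Carlo means over 100 replicates, where this bias is
usually, but not always, within two Monte-Carlo standard errors.

All stochastic outputs are reproducible from a seed; the pipeline writes a
manifest (package version, configuration, seed, outputs) with every run.

## Problem sizes

Defaults throughout are the study-design scale: ~1,100 simulated
individuals, 24 sessions, ~100–300 growth intervals per fit. Monte-Carlo
checks use 100 datasets × 300 intervals (recovery), 1,000 null datasets
(ANOVA type-I calibration), and 100–1,000 seeds for the seasonal and
correlation properties.

## Known limitations

- One interval per individual discards information from intermediate
  captures; a formal increment-likelihood approach (Fabens-style) is out of
  scope.
- No mixed-effects or per-individual growth parameters.
- No survival/abundance estimation from the capture histories.
- Seasonal growth cessation (animals stopping growth during the breeding
  season) is documented in the source literature but has no equation there;
  curves here grow monotonically.
- The bundled prey survey is season-resolved, not month-resolved, so the
  monthly alignment stage applies to dated (e.g. simulated) prey samples
  only.
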