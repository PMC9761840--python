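# Methods

## The model chain

The package predicts mixture lethality from single-chemical bioassays in
four steps.

**1. Probit analysis.** Each group's dead-out-of-exposed count is a
binomial draw with success probability Φ(a + b·log₁₀(level)), where the
level is a concentration (LC-type fits) or an exposure time (LT-type
fits). Fitting is maximum likelihood by Fisher scoring (statsmodels'
binomial GLM with a probit link and group-size variance weights); 0% and
100% groups stay in the likelihood. No natural-response (control
mortality) parameter is included and no +5 offset is added to probits —
the modern convention; median estimates are invariant to the offset.
Completely separated data (every group 0% or 100%, perfectly ordered)
raise `SeparationError` rather than returning a drifting pseudo-fit.
Effective levels ED_p = 10^((Φ⁻¹(p) − a)/b) carry 95% limits from
Fieller's theorem on the fitted line's covariance. When Pearson χ²/df > 1
the covariance is inflated by that heterogeneity factor and the normal
critical value is replaced by t on df — the Finney-style small-sample
convention. When Fieller's g ≥ 1 the limits do not exist and the estimate
is returned flagged; in the 5-level, 10-fish design this happens in
roughly 15% of replicates and those are excluded from coverage summaries.

**2. The log-log lethal-time law.** ln(LT50) = a + b·ln(C) by ordinary
least squares on both axes natural-logged (plain, unweighted — the
simplest model consistent with the data, and errors-in-variables
refinements are out of scope). LT50s longer than the study window, which
are probit extrapolations, are legitimate fit points. Prediction at any
C > 0 is exp(a + b·ln(C)); predictions outside the fitted concentration
range are flagged as extrapolation but not blocked, because extrapolating
to the component doses inside a mixture is the purpose of the law.

**3. Lethal-time addition.** A total mixture concentration is split into
component doses by the *exact* mixing-ratio weights (never by rounded
display proportions — required to reproduce worked values to 4 figures),
and LT50_mix = 1/Σ(Cᵢ/LTᵢ) with absolute component concentrations in
mg/L. The form is harmonic: the result is bounded by min(LTᵢ/Cᵢ),
strictly decreases as components are added, and is permutation-invariant.
A single-component "mixture" returns LT/C, which equals the chemical's
own LT50 only at C = 1 mg/L; the degenerate case is accepted and
documented rather than special-cased, since the rule is only meaningful
for true mixtures. Mixed-unit recipes (a component quoted in µg/L) are
handled by a per-component unit scale applied before any arithmetic, so
all computation happens on one mg/L scale.

**4. Hyperbolic mortality and the predicted LC50.** P(t) =
P₁₀₀·t/(LT50_mix + t) with P₁₀₀ = 100% by default. The default reporting
grid is 24/48/72/96 h; report tables round mortality half-up to integers
while internal values keep full precision. The 96-h mixture LC50 is
obtained by a probit fit of the predicted mortalities against log₁₀ total
concentration, treating each percentage as a quantal response of a
nominal group of 10 — the same analysis an observed bioassay receives,
which is what makes the prediction comparable with an observed LC50. The
alternative route, Brent root-solving of LT50_mix(C) = t on the log axis,
is exposed as a cross-check (`method="invert"`); the two agree within a
few percent on realistic series and exactly when the mortality series is
log-symmetric about the crossing.

**Concentration addition** at effect level x uses the proportion-weighted
harmonic mean LCx_mix = 1/Σ(pᵢ/LCxᵢ) over the 5/15/35/60/90% grid, then
the same probit-on-effect-levels fit for the CA-predicted LC50. The
harmonic form (not a weighted arithmetic sum) is the classical CA model
and is the form that reproduces the worked tables.

**Assessment.** MDR = predicted/observed at full precision, displayed
rounded half-up to 2 decimals. Interaction labels: synergistic (MDR > 2),
additive (0.5 ≤ MDR ≤ 2, boundaries inclusive), antagonistic (< 0.5); the
"valid" compliance band 0.5 < MDR < 2 is reported separately because the
two conventions differ exactly at the boundaries. Toxicity categories use
half-open intervals [0.1, 1), [1, 10), [10, 100) mg/L (highly/moderately/
slightly toxic); values outside are labelled out-of-scheme. Half-open was
chosen because the verbal definitions ("between 1 and 10") are ambiguous
at the edges; a deterministic convention matters more than which one.

## The packaged dataset

`lethaltime.datasets` carries the worked two-species pesticide study:
published log-log coefficients, the per-concentration single-pesticide
LT50s they were fitted from, equitoxic mixing ratios, single-pesticide
LCx tables, observed mixture mortality, and observed/predicted mixture
LC50s. Notes on its internal consistency, established by recomputation:

* Refitting the single-pesticide LT50 points reproduces every published
  (a, b) pair to ~3 decimals. The published r² column mixes plain and
  adjusted R² between rows; tests accept either convention.
* The quaternary mixture's worked tables use proportions derived from the
  single-pesticide LC50s (the equitoxic ratio), not the rounded recipe
  ratio printed with the stock solutions; the dataset stores the
  LC50-derived weights.
* Each published mixture-LT50 cell carries an `include` flag.
  Excluded cells are those the source itself could not have computed from
  its own declared coefficients: the catfish atrazine–mancozeb block
  (component coefficient sets swapped, first row proportion-normalised),
  the tilapia atrazine–lambda-cyhalothrin block (computed with an
  atrazine intercept ≈ 8.805 instead of the declared 8.906, a uniform
  +10.5% offset), and scattered cells that disagree with their own
  printed row inputs. `lethaltime reproduce` recomputes every cell and
  scores only the consistent ones; 52 cells reproduce within 0.5%.
* One published CA table pairs the proportion columns with the components
  in transposed order; `as-printed` mode follows the publication (and
  logs a warning), `strict` mode recomputes with the declared order.
* The observed-LC50 values are carried as inputs: the observed
  mixture-mortality tables do not exactly regenerate them under standard
  probit analysis (the original probit settings are unstated), so the
  package reports both rather than forcing agreement.

## The synthetic generator

`SimulationScenario` draws each organism's death time from a log-normal
law: log₁₀T ~ Normal(log₁₀ exp(a + b·ln C), 1/slope). This is precisely
the tolerance model implied by probit LT50 analysis, so the estimator
chain is consistent on generated data by construction — passing recovery
tests demonstrate correctness of the estimators, not realism of the
model. Features of real bioassays the generator does **not** emulate:
toxicokinetic interaction between mixture components (death times are
per-chemical), between-aquarium variability (duplicates are pooled into
one group of 20), control mortality, and discrete observation artefacts
beyond the hourly census. Deaths after the 96-h window are censored as
survivors; cumulative counts are emitted hourly. One seeded
`numpy.random.Generator` per scenario; identical seeds give identical
tables.

Validation study sizes (chosen to give stable Monte-Carlo summaries at
interactive runtimes): interval coverage uses 500 replicates of a
5-level, 10-fish design with probit slope 3 and levels spanning ±0.5
decades around the true median; large-sample recovery uses 4 000
organisms per concentration with true LT50s inside the observation window
(6–80 h), where the chain recovers (a, b) within 1%; the small-sample
study uses 200 replicates of the 10-fish design, in which the log-log fit
keeps r² ≥ 0.75 in over 80% of replicates. Scenarios whose true LT50s lie
far beyond the window are recoverable only by extrapolation and carry
visible small-sample bias — that is a property of time-censored designs,
not of the estimator.

## Numerical choices

* Probit IRLS: statsmodels defaults, max 100 iterations, tol 1e-10;
  non-convergence raises rather than returning partial estimates.
* Fieller limits solve the quadratic (z−a−bρ)² = c²·Var(a+bρ) directly;
  a non-positive leading coefficient (g ≥ 1) means undefined limits.
* Root-solving for the inversion LC50 runs Brent on log₁₀C with a
  bracket of [min total/10, max total·10] by default.
* Proportions validate to Σp = 1 within 1e-6 at API boundaries and are
  regenerated from exact ratio weights internally (1e-12 consistency).
* CSV dialect is fixed (comma, dot decimal, UTF-8) for bit-exact round
  trips.

## Known limitations

* No toxicokinetic/toxicodynamic interaction modelling: lethal-time
  addition is an additivity reference, and deviations from it are the
  signal the MDR reads, not something the package models.
* No logit/Weibull alternatives to the probit link, and no weighted or
  errors-in-variables variant of the log-log regression.
* Fiducial limits are asymptotic in the Fieller sense; at very small n
  with strong heterogeneity they can be undefined (reported as such).
* The predicted-LC50 probit treats model-generated percentages as quantal
  counts of a nominal group; its confidence limits describe that
  synthetic fit, not sampling uncertainty of a real bioassay.
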