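# Methods

This note documents the models, the synthetic-data design, the numerical
choices and the known limitations of `crrtpk`. It states how quantities are
computed; every empirical number it mentions is one the test suite or the
acceptance script computes at run time.

## One-compartment intermittent-infusion model (`pk_model`)

All kinetics are linear one-compartment with first-order elimination:
during a constant-rate infusion *C*(*t*) = (*R*₀/*CL*)(1 − e^(−*kt*)),
afterwards exponential washout, and superposition across doses. Parameters
are carried as absolute *CL* (L/hr) and *V* (L); reported per-kg values are
converted by body weight before any kinetics (80 kg is used for regimen
simulation of a reference individual). This is appropriate for SBECD — a
~2.2 kDa polymer distributed in extracellular water, not protein bound,
eliminated by filtration (renal or extracorporeal) — and is an accepted
approximation for voriconazole at steady state, though voriconazole's
disposition is genuinely multi-exponential and can be nonlinear (see
Limitations).

**Steady state.** Interval AUC equals Dose/*CL* exactly; troughs accumulate
by 1/(1 − e^(−*k*τ)).

**Time to steady state** is judged on the periodic maintenance component:
the trough after *N* maintenance intervals divided by the steady-state
trough is the accrual fraction 1 − e^(−*k*τ*N*), independent of dose size,
and the first multiple of τ at which it reaches the threshold (default
0.99) is reported. Loading doses are deliberately excluded from the ratio: a
front-loaded regimen (two 1.5× loading doses here) overshoots the
maintenance steady-state trough from the very first interval, so a literal
first-crossing of the ratio would declare "steady state" at 12 h on purely
formal grounds. Time to steady state is a property of the elimination rate
alone — loading changes the magnitude of early concentrations, not the rate
of approach — and the accrual-fraction definition reproduces the expected
~5-half-lives behaviour (48 h at *T*₁/₂ ≈ 6.9 h).

**Population simulation.** Between-subject variability is log-normal on
*CL* and *V* (moment-matched from arithmetic mean/SD: σ² = ln(1 + CV²),
μ = ln m − σ²/2), which guarantees positivity; the distribution family is a
package choice, as the original estimation software's assumption is not
recorded. Residual error is combined proportional + additive,
sd = √((σ_prop·C)² + σ_add²), with a 0.01 mg/L additive floor so that
near-zero predictions keep finite weight. Envelopes (mean, mean ± SD) are
simulated hourly over 0–168 h (first dose through day 7) by default, with
1,000 subjects unless the caller scales down.

## Noncompartmental analysis (`nca`)

- **AUC**: linear-up/log-down trapezoid — linear panel when concentration
  rises or touches zero, log panel (C₁−C₂)Δt/ln(C₁/C₂) on positive
  declines. Chosen as the standard method for post-infusion decline; the
  source analysis specifies only "standard" NCA.
- **λz**: log-linear regression over candidate tails (last 3…k points
  strictly after Tmax, zero and below-quantification samples excluded),
  selecting maximal adjusted R², ties to the longer window. Non-negative
  slopes are discarded; with no valid window the result is flagged not
  estimable rather than imputed.
- **Cmin** is the observed end-of-interval sample; if missing, it is
  extrapolated from the λz fit and flagged (a warning is emitted and the
  interval AUC is completed with a log-down panel).
- **Below-quantification samples** carry the limit in the data table; they
  are excluded from the λz fit, counted at limit/2 inside the profile for
  AUC, and dropped at profile edges.
- **Clearance** at steady state is dose/AUC₀₋₁₂ (per kg when the dose is per
  kg); on day 1 (non-steady-state) the same quantity is reported but flagged
  apparent rather than suppressed. Vd = CL/λz.
- **Dose normalization** rescales metrics to the standard maintenance doses
  (64 mg/kg SBECD, 4 mg/kg voriconazole per 12 h), which makes loading-dose
  day 1 comparable with later days.
- **Accumulation test**: per subject, the day-1 dose-normalized metric is
  paired with the within-subject mean of days ≥ 3 (the aggregation is a
  package choice; the comparison itself — day 1 versus days ≥ 3, classical
  two-sided paired t — is the study's). Identically zero differences report
  t = 0, P = 1; fewer than two complete pairs is flagged not estimable.

## Extracorporeal clearance (`crrt_clearance`)

The **sieving coefficient** is the per-timepoint effluent/plasma ratio,
summarised as median and IQR, computed per subject and then as a cohort
median of subject medians. Ratios are used as measured: no predilution
correction (the clinically reported quantity is the apparent ratio) and no
clipping at 1 (measurement noise legitimately pushes individual ratios
above 1).

**CVVH clearance** is effluent mass recovered ÷ plasma AUC over the same
interval. This rate-over-exposure estimator was chosen over *S*·*Q*_uf
because it is the only construction simultaneously consistent with
reporting "% of dose recovered in effluent" and "fraction of total
clearance", and it needs no predilution assumption; *S*·*Q*_effluent is
retained as a cross-check diagnostic (the two coincide exactly when
effluent ≡ *S* × plasma). Effluent flow is predilution replacement + net
ultrafiltration. At steady state the percent of an interval dose recovered
and the clearance fraction estimate the same ratio; this mass-balance
identity is enforced by test on noise-free cohorts.

## Two-stage population estimation (`poppk`)

Per-subject (CL, V) are estimated by proportional-error weighted least
squares — residuals (obs − pred)/(pred + 0.01 mg/L) — over the full
multi-day profile, minimised by Nelder–Mead on (ln CL, ln V) from a
data-driven start (clearance from Dose/(mean concentration × τ) over the
last interval; rate constant from the terminal slope when estimable) with a
penalty wall at 100-fold either side of the start to prevent escape to
degenerate optima. Fits are deterministic; failures are flagged with
diagnostics and excluded from pooling, never silently replaced. Stage 2
pools log-scale means and SDs per ultrafiltration stratum (2,000 / 3,000 /
6,000 ml/hr) and overall. Two-stage estimation is a deliberate, transparent
substitute for nonlinear mixed-effects machinery: with ten richly sampled
subjects it is standard practice and each stage is independently testable.
Envelope simulation uses the pooled stage-1 residual SD as its output-error
magnitude by default.

## Monte Carlo target attainment (`pta`)

Steady-state free exposure per virtual patient is fAUC₀₋₁₂ =
*f*ᵤ·dose/CL (per kg); loading doses do not affect steady-state exposure,
so maintenance-dose attainment is what is evaluated. Sampling scheme:

| quantity | distribution | default |
|---|---|---|
| CL (L/hr/kg) | log-normal, moment-matched | 0.13 ± 0.06 |
| Vd (L/kg) | log-normal, moment-matched | 3.2 ± 1.5 (sampled for optional trough reporting; does not enter fAUC) |
| weight (kg) | truncated normal on [40, 140] | 81 ± 14 |
| unbound fraction | uniform | 0.36–0.48 (central 0.42) |

Uniform is the least-informative choice for a quantity reported only as a
range; the true sampling families of the original spreadsheet simulation are
not recorded. Per MIC, `n_sim` (default 5,000) fresh patients are drawn and
the percent with fAUC/MIC strictly above target computed; the organism-level
value is the isolate-frequency-weighted mean over the MIC table (frequency
weighting and pooled isolate-level draws coincide in expectation; weighting
is the deterministic construction). MIC values must sit on the two-fold
dilution grid (powers of 2); off-grid values are rejected rather than
snapped. The dose ladder is walked with common random numbers — one draw
set per MIC, fAUC rescaled linearly per dose — which makes attainment
provably non-decreasing in dose and the reported "first adequate dose"
well-defined.

## CYP2C19 stratification (`pgx`)

Star-allele pairs map to phenotype: two loss-of-function alleles (\*2, \*3)
→ poor; one → intermediate (also when paired with \*17); \*1/\*1 →
extensive; \*17 without loss-of-function (\*1/\*17, \*17/\*17) → ultrarapid.
The \*1/\*17 → ultrarapid assignment follows the convention in use before
the separate "rapid" category was introduced, matching the source cohort's
classification. Group comparison is one-way ANOVA by explicit sums of
squares — degenerate cases are then well-defined (zero between-group
variance: F = 0, P = 1; zero residual with a real effect: F = ∞, P = 0;
singleton groups pool into the residual) — with Kruskal–Wallis available
behind a flag. The test behind the original three-group comparison is not
named in the source; ANOVA is the declared default, not a claim about the
original computation.

## Synthetic cohort generator (`synthetic_data`)

The generator is the package's data source and defines the study conditions;
its defaults are not tuning knobs. Per subject it draws weight (truncated
normal 81 ± 14 kg on [40, 140]), CRRT settings (predilution 2,000/3,000/
6,000 ml/hr with probabilities 0.4/0.4/0.2 — chosen so the cohort median
effluent rate lands near the reported ~37 ml/kg/hr — blood flow uniform
200–300 ml/min, hematocrit 0.30, net ultrafiltration uniform 50–250 ml/hr),
PK parameters, and a CYP2C19 genotype (the exact observed counts 6/2/1/1
for n = 10, those frequencies otherwise). Observations follow the study
schedule; residual error is 10% proportional + 0.01 mg/L additive; values
below the 0.05 mg/L quantification limit are stored at the limit and
flagged.

**Clearance structure.** The configured sieving coefficients are *apparent*
(post-predilution) ratios — the observable quantity — with the implied
membrane-level coefficient (apparent ÷ predilution dilution factor
*Q*ₚ/(*Q*ₚ + *Q*_pre)) back-computed into the truth table as a diagnostic.
SBECD clearance defaults to the CRRT-consistent construction
CL = *S*·*Q*_eff/*f* (apparent sieving 0.85, CVVH fraction 0.86), which
reproduces the observed correlation of SBECD clearance with ultrafiltration
rate and makes the configured sieving and fraction exactly recoverable from
noise-free data; an `independent` mode draws CL from the log-normal
0.03 ± 0.02 L/hr/kg instead, for population-recovery studies where the
generating distribution must be known in closed form (the two cannot hold
simultaneously because sieving, flow, fraction and clearance are mutually
over-determined). Voriconazole's extracorporeal removal is parameterised by
its clearance fraction (0.15) with apparent sieving back-computed, since
protein binding makes a fixed sieving coefficient mechanistically wrong for
it. The N-oxide metabolite is generated as a one-compartment species driven
by the parent dose with clearance = (parent/metabolite AUC ratio) × parent
CL, the ratio log-normal with median 2.8; apparent sieving 0.8.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: within-subject parameter variation across
days, filter clotting and treatment downtime, metabolite formation kinetics
(the N-oxide profile shape is an exposure-matched approximation, so its
Cmax ratio tracks its AUC ratio more tightly than in patients), nonlinear
voriconazole elimination, dose reductions, dropout, and assay-specific
error structure. Recovery tests demonstrate that the estimators are correct
under the stated model, not that the model captures every feature of ICU
pharmacokinetics.

## Numerical choices and problem sizes

- Infusion concentrations use `expm1` for small-exponent accuracy; profiles
  are continuous at infusion end by construction.
- Log-down AUC panels compute ln C₁ − ln C₂ to avoid overflow on extreme
  ratios.
- Nelder–Mead runs with xatol 1e-10 / fatol 1e-12; noise-free round trips
  recover parameters to ~1e-4 relative or better.
- Adjusted-R² ties in the λz window break toward more points (1e-12
  tolerance).
- Default problem sizes in the test suite — e.g. 50 replicate cohorts of 10
  subjects for population recovery, 400–2,000 Monte Carlo patients for
  envelope and attainment checks, 5,000 for the analytic-oracle comparison —
  are chosen to make sampling error small relative to the tolerances being
  asserted (3-standard-error bands for stochastic checks) while keeping the
  suite quick to run.
- Pipeline outputs are plain CSV; the run log records seed, configuration
  hash and package version, and identical seeds reproduce every table
  byte-for-byte.

## Limitations

- Reported attainment tables for real organisms depend on the MIC
  distributions supplied; the bundled distributions are synthetic
  stand-ins, so absolute PTA percentages are illustrative, not reference
  values.
- One-compartment kinetics understate early distribution-phase
  concentrations for voriconazole; NCA metrics on simulated voriconazole
  data inherit that simplification.
- Two-stage pooling treats per-subject estimates as exact; with rich
  sampling the shrinkage this ignores is small, but stratum SDs are best
  read as upper bounds on between-subject variability.
- Day-1 clearance estimates are apparent (non-steady-state) by
  construction and flagged as such.
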