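# Methods

## The variability model

`stepvar` treats each subject's daily metric (steps/day, distance, minutes
in an intensity band) as a time series x₁…x_T and summarises its structure
with Poincaré-plot descriptors at delay i (one day by default). For the
lagged pairs (xₙ, xₙ₊ᵢ):

- SD1 = (√2/2)·SD(xₙ − xₙ₊ᵢ) — dispersion perpendicular to the identity
  line; short-term (day-to-day) variability.
- SD2 = √(2·SD(x)² − ½·SD(xₙ − xₙ₊ᵢ)²) — dispersion along the identity
  line; long-term variability. SD(x) is the sample SD of the *whole*
  series, which makes SD1² + SD2² = 2·SD(x)² an exact identity when every
  consecutive pair is used (index mode, lag 1). In calendar mode with
  gaps the identity is only approximate, and the radicand can go slightly
  negative on pathological inputs; it is clipped at zero with a logged
  warning rather than raising.
- SD12 = SD1/SD2, reported as missing (NaN) when SD2 = 0 — 0/0 has no
  meaningful value and downstream correlations drop missing pairs.
- AFE = π·SD1·SD2, the fitting-ellipse area.

All SDs are sample SDs (n−1 denominator); the pair-difference SD uses the
number of pairs minus one.

**Pairing modes.** Wearable data has missing days. A one-day-delay pair
that actually spans a multi-day gap is not a one-day delay, so the default
`calendar` mode emits a pair only when two records are exactly `lag_days`
apart; `index` mode (pairs of consecutive retained records) is provided
for comparison with implementations that ignore dates. `min_pairs`
(default 10) suppresses descriptors from fragmentary series.

## Statistical layer

- **Paired comparisons.** Shapiro–Wilk on the paired differences at
  α = 0.05 (the conventional threshold) gates the test: normality accepted
  → paired t; rejected → Wilcoxon matched-pairs signed-rank (zeros
  dropped, average ranks for ties, exact null for ≤ 25 nonzero
  differences, otherwise normal approximation with continuity
  correction — the mainstream convention). Effect sizes: Cohen's d for
  the paired design is defined on the differences, mean(Δ)/SD(Δ), which is
  identical to the standardised response mean (SRM); the rank-biserial
  correlation (W⁺ − W⁻)/(W⁺ + W⁻) accompanies Wilcoxon. Both mean ± SD
  and median [Q1–Q3] summaries are always populated.
- **Monthly summaries.** "Months" are 30-day blocks counted from each
  subject's first record (subjects enrol on different dates; calendar
  months would misalign them). The mean and SD are pooled over all
  subject-days in the block. The CV is the mean over subjects of each
  subject's within-block SD/mean: subject-level averaging is the only
  reading that can exceed the pooled SD/mean ratio, which published
  tables of this kind do; subjects with a zero within-block mean or fewer
  than two days contribute nothing to the CV.
- **Correlations.** Changes (follow-up − baseline) of each clinical
  outcome against every metric × descriptor column. The `auto` policy uses
  Pearson when Shapiro–Wilk accepts normality for both variables and
  Spearman otherwise; fixed `pearson`/`spearman` policies are available.
  Raw p-values are reported by default; a Benjamini–Hochberg adjusted
  column can be appended (`bh_adjust`). Pairs with zero variance in either
  variable are flagged undefined rather than given an arbitrary r.

## Synthetic cohorts

The generator emulates the study design the package targets: ~30 subjects
wearing a tracker for ~180 days, activity autocorrelated day to day, a
slow decline in steps over the half-year, occasional missing days, and
clinical-outcome changes linearly coupled to activity variability.

Each subject × metric follows a stationary Gaussian AR(1) plus linear
trend. σ is the *marginal* SD (innovation SD σ√(1−ρ²) is derived
internally) and the chain starts from its stationary distribution, so the
closed forms SD1 = σ√(1−ρ), SD2 = σ√(1+ρ), SD12 = √((1−ρ)/(1+ρ)),
AFE = πσ²√(1−ρ²) hold from day 1 and serve as recovery oracles.

Defaults (chosen once to look like a realistic prediabetes cohort; the
published monthly table gives only pooled means/SDs, so these are scale
matches, not fits):

| parameter | default | note |
|---|---|---|
| n_subjects / n_days | 30 / 180 | study scale |
| steps | σ=2800, ρ=0.3, baseline=9900, trend −12.4/day | ≈9900 → ≈8000 steps over six months |
| minutes sedentary | σ=250, ρ=0.3, baseline=830, trend +0.45/day | sedentary time drifts up |
| minutes lightly active | σ=110, ρ=0.3, baseline=280, trend −0.31/day | |
| minutes fairly/very active | σ=12/10, ρ=0.2, baseline=14/9 | low-count channels |
| missing_day_rate | 0.05 | occasional non-wear/sync failures |
| stride | 0.0007 km/step | distance = steps × stride |
| between-subject spread | σ CV 0.4 (lognormal), ρ jitter SD 0.1, baseline CV 0.2 | gives the descriptor variance couplings act on |

Outcome changes are built as
Δ = delta_mean + Σ couplings (coefficient × true descriptor) + noise.
The true descriptors are those of the latent continuous stationary
component: clamping to non-negative integers, the 1440-minute/day cap
(excess trimmed from sedentary first), the trend and missing-day removal
are applied *after* the ground truth is recorded, so estimation error from
those steps is part of what recovery tests measure. The uncentered
coupling shifts the mean change by coefficient × E[descriptor]; the
per-outcome `delta_mean` offset keeps default mean changes realistic
(weight ≈ −1.5 kg, HbA1c ≈ +0.05 %, cholesterol ≈ +0.2 mmol/L over six
months). `coefficient_for_correlation` inverts
r = c·SD(D)/√(c²Var(D)+σ_noise²) to target a population correlation.

What the generator does *not* emulate: wear-time/non-wear classification,
weekday or seasonal harmonics beyond the linear trend, heart-rate or sleep
channels, non-Gaussian heavy tails in daily counts. Passing recovery tests
therefore shows the estimators are correct under autocorrelated Gaussian
data with gaps — not that real tracker data satisfies those assumptions.

## Numerical and design choices

- Sample SD everywhere; descriptor formulas use the full-series SD inside
  SD2 (required for the exact index-mode identity and the degenerate-case
  values).
- Negative SD2 radicand → clip to 0 + warning; SD2 = 0 → SD12 missing.
- Ellipse outlines are generated with `endpoint=False` so polygon-area
  checks (shoelace vs AFE) are exact in the n_points → ∞ limit.
- Duplicate subject-day rows on read: first kept, counted in the
  validation report (deterministic, auditable). Writing rejects
  invariant-violating records outright.
- Fitbit-dialect details (section header, thousands separators, date
  fallback, optional miles→km conversion) are a best-effort reconstruction
  of account exports and are isolated behind the dialect switch; the
  canonical long CSV is the stable interchange format and round-trips
  exactly (floats via `repr`).
- Simulation randomness flows through `numpy.random.SeedSequence` spawns
  (parameters / series / outcomes), so every bundle is a pure function of
  its config, and the subject-parameter draw is independent of the
  coupling settings (a null run at the same seed exposes the same
  subjects).
- Test problem sizes: closed-form recovery uses 10 000-day series over 10
  seeds (sampling error of SD1/SD2 ≈ 1 %, comfortably inside the 5 %
  band); oracle equivalence uses 1000 random series of length 3–50;
  correlation recovery uses 200 subjects × 180 days; the type-I-error
  check uses 1000 null cohorts of 30 subjects.

## Known limitations

- The Poincaré ellipse summarises second-order structure only; asymmetry
  indices, longer delays, and ensemble/attractor methods are out of scope.
- No regression adjustment for covariates, and no imputation of missing
  clinical values.
- Calendar-mode SD2 mixes the full-series SD with pair-restricted
  difference SDs; with heavy missingness the two refer to slightly
  different samples. The index mode and the validation report make the
  effect inspectable.
- The monthly CV definition (mean of per-subject CVs) is a documented
  choice; pooled-SD/pooled-mean is easily computed from the same table if
  preferred.
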