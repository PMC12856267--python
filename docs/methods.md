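# Methods

This note documents the statistical models, defaults and numerical
conventions behind `masld_cua`, and what the synthetic-data tests do and
do not establish about real data.

## Utility mapping

SF-36 produces eight domain scores on 0–100 (physical functioning, role
physical, bodily pain, general health, vitality, social functioning,
role emotional, mental health). When EQ-5D is not administered directly,
a published linear mapping estimates the utility:

    u = 0.03256 + 0.00370·PF + 0.00111·SF − 0.00024·RP + 0.00024·RE
        + 0.00256·MH − 0.00063·VT + 0.00286·BP + 0.00052·GH

Coefficients live in `src/masld_cua/data/sf36_to_eq5d.yaml`; an
alternative algorithm can be supplied as a file with the same layout.
The mapping is affine, so its extremes over the legal score cube are
−0.05444 (positive-slope domains at 0, negative at 100) and 1.13156
(the opposite corner); the all-100 visit maps to 1.04456. Values above
1 are a known ceiling artifact of regression mappings. By default no
truncation is applied — truncation to the EQ-5D UK tariff bounds
[−0.594, 1] is available behind an explicit `clamp` flag, because it is
a reporting choice rather than part of the algorithm. Inputs are
assumed already normalized to 0–100; instrument item scoring is out of
scope. Intermediate values carry full double precision; no rounding.

## QALY gain

Two estimators operate on per-patient utility series:

- **LOCF**: per-patient last-minus-first utility; mean over patients
  with a t-based 95% CI. Patients with one visit are dropped with a
  warning. An area-under-curve variant (trapezoidal mean utility minus
  baseline) is available but not default.
- **Mixed model** (primary): `u_ij = β₀ + β₁·month_ij + b_i + ε_ij`,
  `b_i ~ N(0, σ_b²)`, `ε_ij ~ N(0, σ²)`, fitted by REML
  (statsmodels `MixedLM`). The gain is `β₁ × horizon` (horizon defaults
  to the latest observed month, 8 in the default design) with a Wald CI
  scaled the same way. Random intercept only; no random slope, which a
  27-patient, 5-visit design cannot support.

A utility delta sustained over the one-year program is counted as the
same number of QALYs (0.081 utility points ⇒ 0.081 QALY); no
discounting at a one-year horizon. On balanced noise-free data the two
estimators coincide exactly.

Degenerate fits: when the pooled OLS residual is numerically zero the
data are exactly linear, no variance component is estimable, and the
exact OLS slope with zero SE is returned. Any mixed-model convergence
failure falls back to pooled OLS with a warning. The same slope
machinery serves the expenditure trend model.

## Economics

Program cost is itemized per month (defaults: gym 30, supervision 60,
management 20, insurance 10 ⇒ EUR 120/month, EUR 1,440/year). HICP
adjustment is a pure ratio of supplied index values — indices are
parameters, never fetched, keeping the package network-free; the
base-case EUR 1,440 is treated as already expressed in analysis-year
euros. The comparator is a no-program scenario (C₀ = 0, E₀ = 0),
configurable. `compute_icer` returns a labeled outcome — `ratio`,
`dominant` (ΔC < 0, ΔE > 0), `dominated` (ΔC > 0, ΔE < 0) or
`undefined` (ΔE = 0) — and never raises on a zero denominator.
`NMB(λ) = ΔE·λ − ΔC`; default thresholds EUR 25,000 / 30,000 / 40,000
per QALY. Currency is carried at full precision; rounding happens only
in display.

## One-way sensitivity analysis

Each parameter (QALY gain, cost) is set to the bounds of its range with
the other at base case; entries report the ICER at each bound, the
absolute ICER swing, and the NMB (and its difference from base case)
per threshold, sorted by descending swing. The default ranges — QALY
gain ∈ [0.01, 0.161] and cost ± 20% (EUR 1,152–1,728) — are the pair
that jointly reproduces the published tornado figures (swings of
EUR 135,056 and 7,111/QALY; ΔNMB at 30k of −2,130/+2,400 and ∓288);
they were reverse-engineered from those figures, since the source
ranges are not printed, and are fully configurable. The QALY lower
bound coincides with the PSA implausibility floor and the CI lower
bound's neighborhood; a bound crossing ΔE = 0 is flagged undefined
rather than producing a ratio.

## Probabilistic sensitivity analysis

10,000 draws by default. The QALY gain follows a log-normal
moment-matched to mean 0.081 and SD 0.0408163 — the SD implied by the
reported 95% CI (0.161 − 0.001)/(2·1.96), since no SD is printed. Cost
follows a gamma moment-matched to mean EUR 1,440 with CV 0.20; the
cost dispersion is likewise not printed, and CV 0.20 mirrors the ±20%
one-way range. Moment matching is closed-form:
σ² = ln(1 + sd²/m²), μ = ln m − σ²/2 (log-normal);
shape = m²/sd², scale = sd²/m (gamma).

Dependence comes from a Gaussian copula: standard bivariate normal
draws with correlation ρ = 0.25 are pushed through Φ and then through
each marginal quantile function. The normal correlation parameter is
set to 0.25 directly; the Pearson correlation of the transformed
margins is slightly smaller, which is inherent to copula sampling.
Draws with QALY < 0.01 are excluded as implausible and counted (at the
defaults this removes ≈ 5 × 10⁻⁴ % of mass, so the surviving mean is
essentially unchanged).

Summaries: per-draw ICER = cost/QALY with linear-interpolation
(type-7) percentiles; per-threshold NMB distributions and
Pr(NMB > 0); CEAC on a EUR 20,000–40,000 grid (step 1,000). The CEAC
uses strict NMB > 0; CE-plane ray classification counts points on the
ray as acceptable (NMB ≥ 0) — with continuous marginals the two
conventions agree almost surely. All sampling is seeded;
`scripts/acceptance.py --seed N --out f.json` re-runs the PSA and
reports the three cost-effectiveness probabilities (percent) and the
median ICER.

## Clinical statistics

**Paired continuous markers.** Shapiro–Wilk on the paired deltas gates
the test: p ≥ 0.05 ⇒ paired t, otherwise Wilcoxon signed-rank
(two-sided throughout). All-zero deltas are degenerate and reported on
the Wilcoxon path with p = 1 and a flag. Complete-case analysis; no
imputation.

**Signed-rank conventions.** Zero differences are dropped before
ranking (classic Wilcoxon; Pratt's method is switchable on the
large-sample path). For ≤ 25 non-zero pairs the p-value is exact and
tie-safe: the null distribution of the positive-rank sum over all 2ⁿ
sign patterns, with midranks for tied magnitudes, is built by
subset-sum dynamic programming — identical to full enumeration. This
is implemented in-package because the usual exact algorithm assumes
distinct magnitudes, which ordinal 0–6 steatosis grades rarely give.
Above 25 pairs the tie-corrected normal approximation with continuity
correction is used.

**Steatosis.** Grades are integers on the 0–6 ultrasound score scale
(absent 0, mild 1–2, moderate 3–4, severe 5–6); analysis treats the
score itself as the ordinal variable and reports median (IQR) per arm
alongside the signed-rank p.

**Proportions.** Wilson score intervals (statsmodels), preferred for
small-n binary outcomes; boundary cases k = 0 and k = n hit 0 and 1
exactly.

**Post-hoc power.** Nonparametric bootstrap: resample n deltas with
replacement from the observed delta distribution, test at α = 0.05
two-sided, power = rejection fraction; a power-vs-n curve over a
requested grid uses the same scheme. Post-hoc power is a descriptive
companion to a non-significant result and is reported as such — the
well-known criticisms of observed power apply.

## Drug expenditures

Records are (patient, year, ATC class, cost, packages). Two inclusion
filters mirror two distinct uses: the minimum-package filter (< 3
dispensed packages per patient-class excluded; exactly 3 retained) for
baseline comorbidity profiling, and the consecutive-years filter
(classes with non-zero cohort cost in ≥ 2 consecutive years) for
longitudinal analyses. The filters commute when both apply. Yearly
summaries zero-fill from an explicit patient-year roster so zero-cost
years keep denominators honest; without a roster the observed
patient-years are used with a warning, because real per-year
denominators varied. Classes rank by cumulative cost with
lexicographic tie-break. The trend model regresses per-patient yearly
totals on year (integer offset from the first year ⇒ slope in €/year)
with a patient random intercept (REML), repeated-measures ANOVA as
sensitivity (requires the balanced zero-filled panel). Spending is
analyzed in euros; defined daily doses are deliberately not used, being
unsuitable for intermittent variable-dose regimens.

## Synthetic cohort

Defaults encode the study conditions: 27 patients, visits at months
0/2/4/6/8, latent utility `0.70 + b_i + 0.010125·month + ε` with
σ_b = 0.05 and σ_ε = 0.03 (so the 8-month mean gain is 0.081, and the
noise scale yields CI widths of the reported order); marker pre/post
means and SDs set to the reported blood-pressure and aminotransferase
values with within-patient correlation 0.6 (only marginals are
reported; 0.6 is a realistic default for repeated clinical measures);
steatosis grade vectors centered at median 2 shifting mass toward
grades 1–2 post-program; activity maintenance probability 15/27;
expenditure means EUR 74/71/46/50 per patient-year for 2018–2021 with
30% zero-inflation and gamma CV 0.8, spread over the five ATC classes
(C09BB, C10AX, C02CA, N06AX, R03AK) with most weight on the
antihypertensive class. The baseline utility 0.70 is a typical value
for a middle-aged chronic-disease cohort; per-visit utility means are
not published, so calibration targets the headline gain rather than the
full trajectory.

SF-36 panels are built by inverting the mapping: scores move from the
cube center (all 50) along the fixed direction `sign(β_d)`, scaled so
the affine mapping lands exactly on the latent utility. The corner
direction maximizes the representable utility band
(0.53856 ± 0.713); utilities outside it raise an error naming the band.
This makes the generator an exact right inverse of the mapping — mapped
utilities equal latent utilities to machine precision — at the price of
perfectly collinear domain profiles, which no real questionnaire
produces.

Steatosis pre/post pairs couple through a Gaussian copula on a latent
bivariate normal (correlation 0.6) pushed through each arm's
categorical quantile function; the coupling makes concordant pairs
likely but does not forbid an individual's grade increasing. Zero-cost
expenditure patient-years are emitted as rows (cost 0, packages 0) with
a drawn class label so denominators are explicit; a real dispensing
extract would carry no class for such years. An optional visit-dropout
probability (default 0) exercises the mixed model's tolerance of
missing visits. Everything is deterministic given the spec seed:
identical specs give bit-identical tables.

What passing tests show — and don't: the generator reproduces the
*configured* means, distributions and correlations, so tests establish
that the estimators recover known truth under the assumed structure
(coverage ≈ 95%, calibrated null rejection ≈ α, exact-test agreement
with enumeration). They cannot establish the published p-values or
power (0.828), which depend on the unavailable patient-level data;
those quantities are reproduced structurally, not numerically.
Real SF-36 data would also break the collinear-domain simplification,
and real expenditures are lumpier (few patients dominate a class) than
the gamma model.

## Pipeline and reporting

`run_pipeline` executes the stages in order and writes `results.json`
(schema-versioned, sorted keys, full precision) plus CSV tables
(utilities, tornado, PSA draws, CEAC, clinical markers, year summary).
Outputs are written only after every stage succeeds; a failure raises a
stage-named error and leaves nothing behind. Seeds for every stochastic
stage are recorded in the report; identical config + seeds reproduce
`results.json` byte for byte. Figures are not emitted; the CSV outputs
(CE-plane draws, CEAC grid, tornado entries, class-by-year matrix) are
the plot-ready sources.

Problem sizes in the test suite are chosen to keep the full run fast on
one CPU: coverage checks use 500 simulated cohorts (utility slope) and
300 panels (expenditure trend), null power calibration uses 5,000
resamples, and Monte-Carlo marginal checks use 10⁵–10⁶ draws.

## Known limitations

- The mapping is a group-level regression; individual utilities above 1
  (ceiling) and the single-tariff scope are inherent.
- QALY = utility delta over one year is a modeling convention; longer
  horizons or decaying effects are out of scope.
- The PSA parameterization is moment-matched to reported summaries, not
  fitted to draws; reported-summary quirks (e.g. a PSA mean NMB below
  the base case) are not reproducible from the printed information.
- Post-hoc bootstrap power inherits the circularity of observed-power
  analyses.
- The expenditure model ignores price changes across years and
  class-switching dynamics; no cost offsets (hospitalizations,
  progression) are modeled.
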