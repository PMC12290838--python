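# Methods

This note documents the models, rules and numerical choices behind
`xenocall`, what the synthetic generators do and do not emulate, and the
known limitations of the classification rules themselves.

## Response classification rules

### Patient (RECIST / PERCIST)

Both classifiers operate on a per-treatment course: a baseline scan at
week 0 plus follow-ups at strictly increasing weeks. All thresholds are
strict inequalities — a decrease of exactly 30% is not a PR, an increase
of exactly 20% over the nadir is not progression — and a dedicated
boundary suite asserts that the category never changes at the threshold
itself.

Best-overall-response bookkeeping follows the standard reading: each
follow-up is categorized against the baseline sum (PR/CR) and the
running smallest sum on study including baseline (PD); the course call
is the best category achieved before the first progression. With
`require_confirmation` (default on), a CR or PR seen on only one scan is
downgraded to the best confirmed category and flagged `"unconfirmed"`.
SD needs a qualifying non-PD scan at week ≥ `sd_min_weeks` (default 6);
a course whose only scans precede that interval returns SD flagged
`"not evaluable"`. Lesions are modeled only through the summed diameter
(disappearance ⇔ sum 0); per-lesion bookkeeping and PERCIST SUV flavors
(SUVpeak vs SUVmax, lean-body correction) are out of scope — one scalar
SUV per scan, with CR read from the background/liver flags.

### Mouse PDX trajectories

All volumes are mm³ (0.10 cm³ ≡ 100 mm³, asserted in tests).
"Regression" is measured against the treatment-start volume, not the
running nadir, matching the usual wording of trajectory criteria.
Precedence is MCR > CR > PR > SD/PD; MCR requires at least one
measurement inside the 3-week post-cessation window (no measurement
there disqualifies MCR — conservative). The volume at treatment start is
interpolated when not directly measured; interpolation of volumes and of
threshold crossings (quadrupling, 1,000 mm³ engraftment) is log-linear,
i.e. exponential growth between caliper measurements, which is the
natural interpolant for xenograft kinetics and an explicit, testable
choice. The even-`n` group median resolves to the worse category
(conservative group reporting).

Kaplan–Meier estimation and the log-rank test are delegated to
`lifelines`; closed-form product-limit examples and a hand-computed
tied-data log-rank statistic serve as oracles. A null calibration
(equal exponential hazards, all events observed, n = 60 per group, 2,000
replicates) keeps the empirical type-I error within 0.05 ± 0.02; n = 60
was chosen because the chi-square reference is asymptotic — at n = 15
the true rate of the standard statistic is ≈ 0.059.

### Larval zebrafish PDX

The baseline band is mean ± 1 SEM (sample SD / √n) of the 1-dpi control
counts. Two classification modes implement the two published readings of
the threshold rule: `mean` (default) compares the treated group mean
alone to the band, boundary values inclusive to SD; `interval` compares
the treated group's own mean ± SEM interval and calls SD on any overlap.
The modes coincide whenever the treated SEM is zero.

Dunnett many-to-one comparisons are computed from pooled-variance t
statistics; the family-wise adjusted p-value of arm *i* is
P(max_j |T_j| ≥ |t_i|) under the joint null, sampled by seeded Monte
Carlo (default 100,000 draws) on the exact correlation structure
λ_i λ_j with λ_i = √(n_i/(n_i+n_0)) and a shared chi factor for the
pooled variance. This handles unbalanced groups directly; agreement with
an independent multivariate-t implementation is test-asserted to < 0.01,
and the family-wise error under the null (5 arms × n = 15) calibrates to
0.05 ± 0.02. Per-larva counts are treated as independent observations
(no clutch/plate random effect). The MTD uses a monotone envelope: the
highest dose tolerated *below which every dose is also tolerated*;
tolerated doses above a failing one trigger a warning and are ignored.

### HTS dose–response

The curve model is a four-parameter logistic in log₁₀ concentration,
fit by bounded least squares with multi-start EC50 initialization over
the decade grid (EC50 bounded to the ladder span ± 2 decades, Hill slope
in [0.05, 5]). Replicates are averaged before fitting, so replicate
order is immaterial. `converged` is honest: flat plates (no
improvement over a constant) are flagged and their IC50 censored. The
IC50 is the *absolute* 50%-survival concentration solved from the fitted
curve — not the relative EC50 — and is censored at the ladder maximum
when the curve never crosses 0.5 within [min/10, max×10]. The AUC is the
trapezoidal mean of viability over the log₁₀ ladder span, normalized to
[0, 1]; it can be computed from observed means (plate) or from the
fitted curve on a fine grid (default in the pipeline). IC50 z-scores are
taken on the log₁₀ scale because IC50s span decades; the hit rule
defaults to the conjunction (both z ≤ −2, boundary inclusive) with an
`either` variant as configuration.

## Synthetic generators

The generators exist so every classifier can be exercised against known
ground truth without external data; their defaults mirror the emulated
study conditions (100–200 injected cells, 12–20 larvae per group,
toxicity ladders with n = 16 per dose, 5-point 10-fold dilution plates
in duplicate, caliper schedules twice a week).

*Mouse*: log-volume is `log V0 + g·t − k·min(t, t_regrowth)` — constant
exponential growth g (default one doubling per week) minus a constant
log-kill rate k active until `regrowth_day` (default: end of treatment),
with multiplicative lognormal measurement noise of unit mean and CV
`noise_cv` (default 0.1; caliper-scale noise). Presets realize each of
the five archetypes with comfortable margins (e.g. the PR preset starts
at 300 mm³ so its 60% regression stays measurable; the MCR preset's
nadir of 10 mm³ cannot regrow past 100 mm³ within the 3-week window).

*Zebrafish*: counts are negative binomial with mean μ and size
(dispersion) r, variance μ + μ²/r. The default r = 8 produces the
visibly overdispersed scatter typical of per-larva counts; r = ∞ gives
the Poisson limit; r = 0 is a sentinel for exact deterministic counts
used by zero-noise invariant tests. Variance components are not
reported for the emulated assay, so the default is a realism choice,
not a calibrated one. Arm means are
μ_injected × growth × effect; one root seed spawns an independent child
stream per (arm, day) keyed by a stable label hash, so adding an arm
never changes another arm's draws.

*Patient*: lesion sums are derived exactly from stated percent changes
versus baseline — no randomness.

*HTS*: duplicate wells are the 4PL mean plus Gaussian noise
(`replicate_sd`, clipped at 0); the reference cohort is an empirical
mean/SD over `cohort_n` draws from the stated cohort distributions.

What the generators do **not** emulate: engraftment-failure biology,
pharmacokinetics of immersion uptake, inter-mouse growth-rate
heterogeneity, clutch effects in larvae, or plate artifacts (edge
effects, drift). Passing recovery tests therefore demonstrates that the
classifiers invert the stated generative rules under realistic noise —
not that they are robust to every failure mode of real assays.

## A statistical limitation of the ±1 SEM band

The zebrafish SD call asks whether the treated group mean falls inside
the control mean ± 1 SEM. But the band half-width *is* the standard
error of the band's own center, and the treated mean carries comparable
sampling noise. For independent groups with matched means, the
probability of an SD call is P(|Z|·√(1+v) ≤ 1) with v the ratio of the
treated-mean variance to the control-mean variance: at most Φ(1) − Φ(−1)
≈ 68% (as v → 0), ≈ 52% at equal sizes and dispersion (v = 1), and at
most ≈ 84% for the interval mode. This ceiling is distribution-free —
independent of the count level, dispersion and group size — so a truly
static tumor is classified SD only about half to four-fifths of the
time; only exactly noiseless counts classify SD reliably. The synthetic
recovery suite documents this: kill and growth regimes recover R/PD in
≥ 95% of seeds, while the neutral regime plateaus near the ceiling. It
is a property of the published band rule, not of this implementation.

## Problem sizes and numerical defaults

Calibration experiments use 2,000 replicates (Monte Carlo SE ≈ 0.005 on
a 0.05 rate); Dunnett null sampling uses 100,000 draws (SE ≈ 0.0007 at
p ≈ 0.05); the trajectory-classifier oracle grid covers ≈ 12,000
3-point trajectories including exact boundary values; recovery rates use
100 seeds per condition. Ties in the group median resolve to the worse
category; band boundary values resolve to SD; z = −2 resolves to hit.
Degenerate inputs (constant ANOVA data, flat plates, no events in either
survival group, zero-variance bands) return explicit, documented calls
rather than errors wherever a call is well defined.
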