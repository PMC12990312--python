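# Methods

## Scope and model

`faerspv` analyses spontaneous-report databases of the FAERS family for
one target adverse event (by default the preferred term "Proteinuria").
The statistical object is the per-drug 2×2 table (a, b, c, d) over
deduplicated reports, with the drug margin restricted to primary-suspect
(PS) mentions: a report contributes to a drug's exposed row only when
that drug is its primary suspect; reports whose drugs are all
non-suspect still contribute to the background margin, because the
disproportionality background must cover the whole database. A report
with several PS drugs contributes one count to each drug's table.

## Disproportionality statistics

Frequentist measures follow their textbook definitions: ROR = ad/bc with
the Wald interval exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)); PRR =
[a/(a+b)]/[c/(c+d)]; the χ² is the plain Pearson statistic
N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) *without* Yates continuity correction —
the uncorrected form is what reproduces the published χ² values on the
reconstructed tables — with Yates available as an option. Cells are held
as floats: reconstructed tables are real-valued, and N·(ad−bc)² overflows
64-bit integers already at moderate database sizes.

Zero cells make ROR/PRR undefined; they are returned as NaN and flagged,
with the Haldane–Anscombe +0.5 correction on all cells available as an
opt-in. NaN statistics make the corresponding signal flag false and are
listed as not evaluable rather than silently dropped.

The information component is IC = log₂(a/E) with E = (a+b)(a+c)/N. Its
lower bound IC025 uses Norén's closed-form approximation
IC − 3.3·a^(−1/2) − 2·a^(−3/2) by default; the fully Bayesian Bate-1998
estimator (Dirichlet-type priors, normal-approximation interval) is an
alternative mode. The two differ by a few hundredths of a bit at large
a; published tables rarely state which variant they used, so both are
exposed.

### MGPS / EBGM

The empirical-Bayes model is the DuMouchel gamma-Poisson shrinker:
a ~ Poisson(λE) with λ ~ w·Γ(α₁,β₁) + (1−w)·Γ(α₂,β₂) (shape/rate).
Marginally a is a two-component negative-binomial mixture; the five
hyperparameters are fitted by maximizing the summed marginal
log-likelihood over all drug–event pairs. The optimizer works in log
parameters (logit for w) with L-BFGS-B, bounds ±12 on the log scale,
relative tolerance 1e-8, and five starts: DuMouchel's classical initial
value (0.2, 0.1, 2, 4, 1/3) plus seeded unit-normal perturbations. The
best optimum is returned; an error carrying the best-so-far prior is
raised only if no start converges. The mixture is unidentifiable up to
component relabeling; consumers that compare against known components
should sort components by prior mean.

The posterior of λ given a is again a two-gamma mixture with weight
Q ∝ w·NB₁(a). EBGM = exp(E[ln λ | a]) using E[ln Γ(s, r)] = ψ(s) − ln r,
and EBGM05 is the 5th posterior percentile found by Brent root-finding
on the analytic mixture CDF (xtol 1e-12, upper bracket doubled until it
covers the quantile). At large (a, E) with fixed a/E the posterior
concentrates and EBGM → a/E, which is why a published EBGM of 37.93 next
to an observed/expected ratio of 37.93 is the expected large-count
behaviour rather than a coincidence.

### Consensus

A drug is a consensus signal when all four methods pass their classical
thresholds: a ≥ 3 and ROR CI lower > 1; PRR ≥ 2, χ² ≥ 4, a ≥ 3;
IC025 > 0; EBGM05 > 2. All thresholds are configurable
(`SignalCriteria`); the conjunction is deliberately conservative, so
weakly planted drugs (θ ≲ 3 at desk-scale counts) are *not* expected to
reach consensus — the EBGM05 > 2 clause alone requires a posterior
confidently above twice the background.

## Algebraic table reconstruction

Published signal tables print derived columns but not b and d. With
c = event_total − a fixed, the ROR and PRR identities are linear in the
remaining cells: b = a(PRR−1)/(ROR−PRR) and d = ROR·b·c/a. The solve is
rejected when ROR = PRR (singular) or a solution is nonpositive, and the
result is verified against both identities to 1e-9 relative before
being returned unrounded. Recomputing CI bounds, χ², IC and a/E from the
reconstructed table checks a published table's internal consistency
using only printed numbers.

## Ingest

FAERS quarters are "$"-delimited ASCII with a header row; columns are
taken from the header, not position, and rows with the wrong field count
are counted and skipped, never fatal (a missing primaryid/caseid column
in DEMO is fatal). Deduplication keeps, per caseid, the version with the
latest receipt date, ties broken by the larger primaryid — the
convention FDA documents for case amendments. Ages are converted to
years (DEC×10, MON÷12, WK÷52, DY÷365.25, HR÷8766), weights to kg
(LBS×0.453592, GMS÷1000); values outside [0, 150] years or (0, 700) kg
and unknown unit codes become missing with a logged warning. Partial
dates are completed deterministically (YYYYMM → the 15th, YYYY → July 1)
and flagged imprecise so onset analyses can exclude them. Drug names are
case-folded, whitespace-collapsed, salt/ester suffixes stripped, and
mapped through a small packaged brand→generic synonym table that users
can extend; unmapped names pass through case-folded.

## Regression cascade

The design matrix has one PS indicator per drug (alphabetical) plus
covariates coded as: sex male vs female (reference); age in five classes
<18 (reference), 18–40, 41–60, 61–80, >80; weight inside 50–100 kg
(reference) vs outside. Only complete cases enter. The univariate screen
retains drugs with a > 100, ROR 95% CI lower bound > 1, and
Benjamini–Hochberg-adjusted single-predictor logistic p < 0.01; the BH
family is the set of drugs passing the count gate, and the
disproportionality clause can be switched to the ROR point estimate.

LASSO selection is an L1-penalized logistic model over the retained drug
indicators with the demographic covariates kept unpenalized — penalizing
reference-coded adjustment variables would distort selection. The solver
(liblinear) has no per-column penalty factors, so unpenalized columns
are inflated by 100× before the fit and the coefficients rescaled after;
this divides their penalty contribution by 100, which is numerically
equivalent to a zero penalty factor here. The λ path is 20 points,
log-spaced over three decades below the null-gradient λ_max; 10-fold
stratified, seeded cross-validation of binomial deviance picks λ_min and
λ_1se (the largest λ within one standard error of the minimum), with
λ_1se the default selection rule. An empty selection is a warning, not
an error.

The multivariate fit is plain maximum-likelihood logistic regression
(statsmodels) over the selected drugs plus covariates, reporting Wald
ORs, 95% CIs and p-values; drugs with p < 0.01 are labeled significant.
Newton occasionally reports non-convergence while sitting at the
optimum (step-halving oscillation); fits whose score vector is
numerically zero (max |gradient| ≤ 1e-3) are accepted. True separation
(infinite standard errors) raises with the offending terms named. AUC is
computed from the tie-corrected Mann–Whitney rank statistic, with the
ROC curve emitted at every distinct threshold.

## Time to onset

Onset is event date minus the PS drug's earliest therapy start, in days.
Negative onsets and onsets beyond 25 years (9125 days) are excluded as
data errors; records with imputed (imprecise) dates are excluded by
default and includable by flag. Per-class summaries report n, the
arithmetic mean, and Q1/Q3 by linear interpolation between order
statistics (numpy's default convention; the choice is documented because
printed quartiles cannot adjudicate a convention without raw data).
Cumulative incidence is the ECDF evaluated on a shared day grid.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, with known
ground truth. Each case draws one PS drug from a catalog of
(name, share, θ, onset median, onset log-SD); the target event occurs
with probability p₀·θ(drug) (configs with p₀·max θ > 1 are rejected), so
θ is the true rate ratio. Background PTs (1 + Poisson) from a 24-term
pool are assigned independently; concomitant mentions (role C) are drawn
at rate 0.3/case. Onsets are log-normal per drug — positive,
right-skewed, two parameters. Demographics mirror the published baseline
table of proteinuria reports: sex 44/38/18% male/female/missing, ~8%
pediatric mass uniform on 0.5–17.5 years over an adult Normal(62, 16),
weight Normal(74, 16) kg with 25% missing, age/weight written in mixed
FAERS unit codes (DEC/MON/DY, LBS/GMS) to exercise the parser, country
weights with the US and Japan dominant, 5% partial dates, receipt
lagging the event by 7–120 days. Duplicate case versions (default rate
0.05) get a new larger primaryid, a later receipt date and amended
fields; the ground truth records the latest version per case, so
deduplication can be verified exactly.

The default catalog plants the published 21 proteinuria drugs with rate
ratios on the scale of their published RORs (voclosporin 60, lenvatinib
40, … down to 2.2) over 30 null background drugs, with
p₀ = 0.012 and a default cohort of 60,000 reports — large enough for the
strongest three drugs to clear the a > 100 screen gate while keeping a
full pipeline run around a minute.

Two output paths exist: `generate_reports` writes the quarterly
"$"-delimited files (byte-identical for a fixed config and seed), and
`simulate_store` builds the equivalent in-memory case store directly
from the same sampling core, skipping the ASCII round trip; the
replicate-based simulation studies use the fast path, while the file
path is exercised by its own round-trip tests.

What the generator does *not* emulate: reporter-country biases,
indication-driven channeling (confounding by indication), correlated
event co-reporting, dose records, duplicate reports with conflicting
demographics beyond field completion, and MedDRA hierarchy structure.
Passing tests therefore demonstrate statistical correctness of the
machinery under the stated model, not robustness to the full messiness
of real FAERS.

## Simulation study sizes

Calibration and recovery suites are sized to keep the full test run in
minutes on one core: hyperprior recovery uses 50,000 simulated
(a, E) pairs; null calibration uses one 100,000-report cohort with 200
null drugs plus 100 outcome permutations of a 60,000-report cohort;
planted-signal recovery uses 100 seeded replicates of 100,000 reports
with θ ∈ {5, 10, 40} planted at 1–1.5% share over 47 null drugs and
p₀ = 0.02. Those values are chosen so that (i) the weakest planted
drug's expected case count, ~150, clears the a > 100 gate, (ii) the
strongest drug's event probability p₀·θ = 0.8 stays away from the
degenerate b = 0 regime, and (iii) total event contamination from the
planted drugs keeps observed/expected ratios of true signals well above
the consensus thresholds; TTO recovery uses ≥ 2,000 onsets per class.

## Known limitations

- MGPS expected counts are unstratified; age/sex/year stratification of
  E is out of scope.
- The BCPNN IC025 is an approximation; the exact posterior quantile of
  the Bate model is not implemented (both published variants are, and
  they bracket typical printed values).
- The LASSO penalty-factor trick reduces, rather than exactly zeroes,
  the covariate penalty (factor 1/100); with standardized binary
  covariates the residual shrinkage is far below the Wald CI width of
  any reported coefficient.
- Real-data quantities that depend on the actual FAERS database (total
  report counts, published AUC, absolute onset quartiles) are out of
  reach by construction; the pipeline reports them for whatever data it
  is given.
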