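# Methods

This note documents the statistical machinery, the synthetic-data model, and
the design choices made where the published methodology leaves the design
open.

## Scoring (WPAI:SHP v2)

The six items are employment status (Q1), hours of work missed due to
migraine (Q2), hours missed for other reasons (Q3, carried but never
scored), hours actually worked (Q4), and two 0–10 impairment ratings for
work (Q5) and non-work activity (Q6), all over a 7-day recall. Scores are
time-lost ratios expressed as percentages. Decisions:

* Work scores exist only for employed respondents; activity impairment for
  everyone.
* A domain is undefined when any item it needs is missing (complete-case
  policy per domain), and when its denominator vanishes: Q2 + Q4 = 0 leaves
  absenteeism/overall undefined, Q4 = 0 leaves presenteeism undefined.
* Q2 > 0 with Q4 = 0 is total loss: absenteeism = overall = 100.
* Scores are kept at full float precision; rounding (2 dp) happens only when
  report tables are serialized.

## Diary

A migraine day needs ≥ 30 min duration, ≥ 2 of 4 pain characteristics
(condition A) and ≥ 1 associated symptom — nausea/vomiting, or photophobia
with phonophobia (condition B). *Probable* migraine is operationalized as
exactly one feature short: A holding while B fails entirely, or B holding
while A has exactly one characteristic. Aura is ignored. Both classes count
as migraine headache days.

Monthly aggregation uses consecutive 30-day windows anchored at
randomization (the baseline window ends the day before; Month 3 is days
61–90). With x recorded days the raw count is prorated by 30/x; a month is
missing when strictly more than half its days are unrecorded
(30 − x > 15). Headache days are prorated identically (configurable) since
the subtype rule compares them with fixed day counts.

Subtype: CM is ≥ 8 MHD with ≥ 15 total headache days; EM is anything else
with ≥ 4 MHD (including 4–<8 MHD with 15–29 headache days); < 4 MHD is
ineligible for this population.

## Anchors

MSQ-RFR ≥ +25.71 points, MSQ-RFP ≥ +20.00 points, MHD reduction ≥ 50 % of
baseline, all over baseline → Month 3, boundary inclusive. Worsening is a
non-response, never an exclusion; only a missing value (or a zero MHD
baseline, where a relative reduction is undefined) removes a subject from an
anchor's analyses. The MHD50 anchor uses the prorated Month-3 window alone;
whether a Months 1–3 average was intended is ambiguous in the source
methodology, and the single-window choice keeps the anchor aligned with the
diary windows the package simulates.

## Reliability

Test–retest uses placebo subjects with |ΔMHD| ≤ 1 day (prorated values,
inclusive). The random-intercept-only model is estimated by REML via
`statsmodels.MixedLM`; optimizers are tried in the order BFGS
(gtol = 1e-10), L-BFGS, Powell, because the default optimizer can stop
short of the 1e-6 agreement we require with the balanced-design ANOVA
estimator `(MSB − MSW)/(MSB + MSW)` and can fail outright on very small
subgroups. Negative variance estimates are truncated at zero; an
all-identical-scores input yields an undefined ICC with a warning. Band
labels are applied after rounding the ICC to 2 decimals, so the printed band
boundaries (0.20/0.21 and so on) are unambiguous.

## Validity

Spearman ρ (midranks for ties, ≥ 3 complete pairs) between baseline WPAI
domains and the continuous anchors. Two band schemes are kept because the
source methodology uses both: `validity_report` (seven levels from
negligible-low to high) is the output default, `anchor_selection` adds a
"very high" level above 0.90. Boundary values go to the upper band.
Anchor eligibility is |ρ| ≥ 0.30 — absolute value because WPAI (higher =
worse) scores opposite to MSQ (higher = better). Configured anchors that
fail the screen are flagged, not dropped.

## Responsiveness

OLS ANCOVA `change = β₀ + β₁·responder + β₂·baseline`, pooled across arms.
LS-means are predictions at the grand mean of baseline over included cases;
the LSM difference (non-responder minus responder) equals −β₁ exactly in
this additive model. p-values use the t distribution with n − 3 df,
two-sided at 0.05, without multiplicity adjustment. Absenteeism is excluded
from this stage (and from thresholds): its scores and changes are too small
and too weakly anchored for a standalone responder analysis.

## Thresholds

Improvement is a negative change; predicted responder iff change ≤ c (the
convention that exactly reconstructs the published PPV/NPV from the printed
sensitivity/specificity and responder counts). The candidate cut-off set is
the union of observed change values and a fixed 10-unit grid from −60 to 0.
The per-anchor optimum maximizes the Youden index, ties broken toward the
smallest |c| (most conservative threshold). The cross-anchor consensus rule
formalizes "YI high for all anchors" as max–min: candidates are the grid
values (cut-offs rounded to the grid step) supported by every anchor; each
anchor contributes the YI of its row nearest the candidate; the candidate
with the largest minimum wins, ties again toward the smallest magnitude.
Misclassification at a threshold is 1 − specificity at the nearest grid
row. AUC is computed as the Mann–Whitney concordance (ties ½) — well-defined
even under complete separation, where the logistic coefficients are flagged
non-converged — and banded as poor / good (0.7) / excellent (0.8) /
outstanding (0.9). eCDF curves are right-continuous; their vertical gap at x
equals YI(x), making the Youden optimum the Kolmogorov–Smirnov point.

## Synthetic-data model

The generator emulates the trial features the pipeline consumes, not the
trial itself:

* **Design**: n = 444 subjects (the analysis population), 1:1
  placebo/active, CM fraction 183/444, employed fraction 315/444, two
  visits, two 30-day diary windows.
* **Baseline**: one latent severity factor (loading 0.5 of each measure's
  sd; positive for WPAI and MHD, negative for MSQ) induces the
  cross-sectional correlations the validity stage screens for; marginals
  are truncated normals at the published overall-population moments
  (presenteeism 42.75 (23.24), activity 50.97 (23.91), MSQ-RFR 45.05
  (17.16), MSQ-RFP 63.78 (19.15); MHD by subtype: EM 9.30 (2.84) on [4,14],
  CM 18.58 (4.72) on [8,29]).
* **Change**: one latent improvement factor f ~ N(arm·δ, 1) with δ = 0.9
  for the active arm; each measure's change is loading·f plus independent
  noise (WPAI loadings 15, noise 14; MSQ loadings 15–16, noise 13; MHD
  loading 4, noise 3). These loadings give change-score correlations ≈ 0.5
  and concordance AUCs in the published 0.7–0.8 range. `true_mwpc`
  (default 20) rescales the WPAI loadings so the expected WPAI improvement
  at the MSQ-RFP responder boundary equals the configured threshold, which
  recovery tests can look for.
* **Items**: WPAI items are built backwards from target domain scores
  (Q5/Q6 rounded to 0–10, hours chosen so the absenteeism ratio matches),
  so generated scores are integer-grid valued like real WPAI data.
* **Diary**: each day is a migraine headache day with probability MHD/30
  (a quarter probable migraine), a non-migraine headache day with
  probability (HD − MHD)/30; features are drawn to satisfy — or fail by two
  features — the migraine definition. Only monthly counts matter
  downstream.
* **Missingness**: completely at random — Month-3 item cells at 8 % (the
  published complete-data attrition ≈ 26/315), diary days at 2 %.

What it does **not** emulate: dropout over time, informative missingness,
within-month headache clustering, the open-label period, and the real
baseline correlation matrix beyond the single-factor approximation. Passing
pipeline tests on this generator therefore demonstrates the machinery's
arithmetic and invariances, not real-data effect sizes.

## Problem sizes and determinism

Unit and pipeline tests run at 60–444 subjects; the ICC parameter-recovery
check uses 2000 subjects × 2 visits, where the REML estimate of a 0.446
variance share is reproducibly within ±0.03. All randomness flows through
`numpy.random.default_rng` seeded from the configuration, and rerunning any
stage with the same seed reproduces byte-identical CSVs.

## Known limitations

* The consensus rule's nearest-row evaluation depends on the candidate grid
  resolution; on dense observed-value grids the max–min selection can land a
  grid step away from the single-anchor optimum when one anchor's Youden
  curve is flat (the MHD50 anchor, being a relative reduction, is flattest).
* ICC fits on very small stable subgroups (a handful of subjects) are
  reported but carry large sampling error, mirroring the instability such
  subgroup analyses have in practice.
* The logistic fit is reported alongside the AUC for completeness; the
  threshold search itself uses only the empirical classification table, so
  separation or non-convergence does not affect the selected cut-offs.
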