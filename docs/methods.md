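# Methods

This note documents the statistical procedures, their assumptions, the
defaults that matter, and the design choices made where the design was
genuinely open.

## Questionnaire scoring

EORTC domains use the standard linear transformation. With raw score
`RS` = mean of the answered items of a domain and `r` the item range
(3 for 4-point items, 6 for the 7-point global-health items):

- functional domains: `score = 100 · (1 − (RS − 1)/r)` (higher = better),
- symptom domains and global health status: `score = 100 · (RS − 1)/r`.

A domain is scored only when at least half its items are answered (half
rule); `n_items_answered` is always reported. The summary score reverses
symptom domains (`100 − score`) and averages the 13 summary-eligible
QLQ-C30 domains (global health status and financial difficulties
excluded), so 100 is always best. By default all 13 components must be
present — this matches the completion-rate definition ("enough completed
items to compute the summary score") — with a relaxed `min_domains` mode
available but off by default.

Two transforms coexist deliberately: domain analyses use the exact
transform (e.g. 33.33 for a single-item "a little"), while symptom
dichotomization uses the conventional printed integers 0/33/67/100. The
≥ 33 and ≥ 66 cutoffs are defined on the printed scale, so "quite a bit"
(67) counts as moderate/severe.

The FACT/GOG-Ntx subscale reverses each 0–4 item (`4 − response`), sums
the answered reversed items, and prorates by `11 / n_answered`, requiring
at least 6 of 11 items (the ≥ 50% rule of the FACT scoring convention).

Item-to-domain maps ship as a versioned data file
(`data/instrument_spec.tsv`), so instrument-version drift is a data
change, not a code change.

## Utilities

The QLU-C10D descriptive system is derived from QLQ-C30 items: for
multi-item dimensions the level is the most severe (highest) answered
response (worst-of rule); single-item dimensions pass through. A
dimension with no answered item makes that visit's utility absent; this
mirrors the spirit of the scoring half rule while never fabricating a
level. The worst-of rule is isolated in `items_to_dimension_levels` so an
alternative derivation can be swapped in without touching the pricing.

Value sets are data: a TSV of (dimension, constituent items, level,
decrement) validated at load time — exactly 10 dimensions × 4 levels,
level-1 decrements zero (so the all-best state prices at exactly 1), all
decrements non-negative and non-decreasing in level. The packaged file is
a **synthetic** tariff satisfying these invariants with a worst-state
utility of −0.15; it exists so the engine is runnable and testable
end-to-end, and it is not a substitute for a published country valuation.
Utilities below zero are retained (not floored) and propagate to the
quality-adjusted survival times with a warning; `floor_at_zero` exists
for sensitivity analyses.

## Responder analyses

Change from baseline is classified improved / stable / worsened against a
threshold of 20 points (33 for single-item body image), signed in the
domain's improvement direction; a missing baseline or follow-up makes the
visit unclassifiable, and the four categories partition the patients with
a score row. Arm contrasts use the chi-square test of homogeneity without
continuity correction and a Woolf-interval odds ratio, with the
Haldane–Anscombe 0.5 correction applied (and flagged) on zero cells.

Time to first improvement censors never-improvers at end of study and
excludes patients who cannot express a full-threshold improvement:
missing baseline, functional/global-health baseline above 80 points, or
body-image baseline above `100 − 33 = 67`. The body-image cutoff is
derived from the no-arithmetic-room principle rather than the scale's
problem direction, because body image is functionally oriented (high =
good); the exclusion rule set is argument-driven for sensitivity
analyses. The arm contrast is a Cox proportional-hazards model with
treatment, baseline score and country as covariates.

"Developed a symptom during the study period" is operationalized as
cumulative incidence: among patients below the cutoff at baseline, any
post-baseline visit at or above the cutoff counts, evaluated at both
severity cutoffs. Per-visit proportions are also emitted so either
reading of "developed" is available. Symptom–item sets (including the
restlessness/agitation item of the myeloma module) are configurable data.

## Quality-adjusted progression-free survival

Per patient, `QAPFS_i = PFS_i × q̄_i`, with `q̄_i` the mean of all
available on-protocol assessments *including baseline* of either the
summary score / 100 or the QLU-C10D utility. Censoring times are
quality-adjusted identically to event times, keeping KM risk sets
internally consistent.

The group-level "KM mean" is implemented as the restricted mean: the area
under the Kaplan–Meier curve up to the largest observed time in the arm
(the restriction time is data-driven because no fixed horizon is part of
the estimand). Its variance is the Greenwood-type sum
`Σ_j A_j² d_j / (n_j (n_j − d_j))` with `A_j` the curve area beyond event
time `t_j`; the per-arm CI is the normal interval on that SE. Without
censoring the estimator equals the arithmetic mean exactly (tested).

The between-arm difference is a percentile bootstrap: patients resampled
with replacement within arm, the restricted mean recomputed per
replicate (minimum 1,000 replicates, default 2,000), two-sided p-value
`2 · min(P(diff ≤ 0), P(diff ≥ 0))` floored at `2/n_boot`. Replicates in
which an arm loses all events are redrawn and counted. Both the
KM-variance CI and the bootstrap CI are emitted, since either convention
is defensible for the arm means.

## Longitudinal models

The change model is an MMRM: response is change from baseline at each
post-baseline visit up to the analysis horizon (default month 8), fixed
effects categorical time, arm, **arm × time**, and country, random
intercept per patient, REML. The interaction is required — without it the
per-timepoint arm contrasts the analysis reports are inexpressible.
Missing data are handled by the likelihood (valid under missing at
random); no imputation. Adjusted means average country effects over the
observed country distribution. Singular or non-converged fits downgrade
to an independent-errors OLS fit with a warning. The contrast flags
follow a two-step logic: statistical significance at the configured α
(default 0.05; some analysis plans reserve 0.01 for the primary
endpoint, so α is a parameter), and — only for significant contrasts —
clinical relevance when |estimate| reaches the domain's MID. MIDs live in
`data/mid_thresholds.tsv`: 10 points for the summary score, the
recommended myeloma-module values (10/10/13/9), 4.4 for the
neurotoxicity subscale (11.8 as sensitivity), and representative
small-difference thresholds for the core-questionnaire domains.

The supportive comparison averages each patient's available summary
scores (a single assessment is its own average) and applies the
two-sided Wilcoxon rank-sum test to the per-patient averages.

Pattern-mixture diagnostics stratify by dropout time — early (off
protocol by month 8), late (on study at month 10), never (on protocol at
end of study) — and, within each arm, fit a mixed model of the score on
stratum and categorical time. A negative early-vs-late contrast means
early dropouts reported systematically worse HRQL: evidence against
ignorable dropout. Both the 2-stratum (late pools late + never) and
3-stratum versions are emitted; empty strata yield flagged, skipped
contrasts rather than errors.

Completion rate is the fraction of on-protocol patients (last follow-up
at or after the visit) whose responses permit a summary score, per visit
and pooled. A roster utility computes the last analysis visit before
either arm's on-protocol count drops below 15.

## Synthetic-trial generator

The generator emulates the structure the analyses assume, not any real
patient data. Latent domain trajectories are
`baseline + slope_arm · min(t, 8) + AR(1)` with baselines drawn from
arm-specific normals (Table-of-baselines defaults: e.g. global health
66.0 SD 22.3 vs 68.1 SD 18.8) truncated to the scale, a shared
patient-level factor inducing between-domain correlation (default 0.5,
sign-flipped for symptoms), AR(1) noise (SD 9 points, ρ 0.6), and
arm-specific linear recovery to month 8 taken from the default 8-month
change table (the maintenance arm recovers more slowly). Items are
emitted per visit by adding small per-item jitter (SD 4) and rounding the
implied raw score to the nearest Likert level — equal-width cut-points —
so re-scoring recovers the latent mean within one discretization step
(≤ 16.7 points for 4-point items), exactly invertible at zero noise.

PFS is Weibull (shape 1.2, a mild aging hazard; only the medians — 19.3
and 16.8 months — are calibration targets). Dropout mechanisms:
`progression` (follow-up ends at progression or end of study),
`mcar` (adds a score-independent per-interval hazard, default 0.03), and
`mnar` (multiplies that hazard by 10 whenever the current latent summary
is below 78 points). The MNAR preset was calibrated so that the
2-stratum early-vs-late summary contrast it induces is ≈ −12 points at
the default design — the magnitude an informative-dropout diagnostic is
expected to reveal in this setting — making the diagnostic's power
testable. Questionnaire compliance thins whole visits at 0.93.

`truth_report` records the generating arm effects, the analytic
restricted-mean PFS per arm (Weibull survival integrated to the horizon)
and the implied true QAPFS (survival and quality are independent under
the generator, so the product of expectations is exact up to scale
clipping).

What the generator does **not** emulate: per-item heterogeneity within a
domain (items share the domain latent), visit-date drift (assessments are
keyed to nominal months), country effects on outcomes (country is a
label), and correlation between progression risk and HRQL level. Passing
tests therefore certify the estimators' arithmetic and calibration under
these stated conditions, not the behaviour of real trial data.

## Numerical conventions and problem sizes

Ties in the KM computation put events before censorings. Normal (z)
intervals are used for mixed-model contrasts and log-odds ratios.
Mann–Whitney uses scipy's exact/asymptotic switching. All analyses are
deterministic given seeds; the bootstrap and simulator require explicit
seeds. Test-suite simulation sizes were chosen to keep the full suite
within a few minutes on one CPU while leaving the Monte-Carlo bands
discriminating: 200 replicates for bootstrap-coverage and
parameter-recovery checks, 1,000 for type-I-error calibration, 25 for
the MNAR-power check (n = 80/arm each).

## Known limitations

- The packaged value set and instrument coding are synthetic stand-ins;
  substantive use requires the published instrument coding and a
  published country tariff.
- The restricted-mean restriction time is the largest observed time per
  arm, so arm means are not strictly comparable when follow-up differs
  grossly between arms (the bootstrap difference inherits this).
- The MMRM downgrade path (OLS) changes the standard errors, not just
  the point estimates; downgrades are flagged in the output.
- Negative utilities produce negative quality-adjusted "times"; the KM
  machinery handles them, but the estimand is then hard to interpret —
  the warning is deliberate.
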