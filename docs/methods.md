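# Methods notes

This note records the models, conventions, and design choices behind the
package, in the spirit of a statistical appendix: what is computed, under
which assumptions, and where judgment calls were codified.

## Instrument model

The QOL-E has 29 items. Items 1 (overall health: poor/acceptable/good/
excellent) and 2 (health compared with a month ago) describe general
well-being and never enter a scored scale; Item 1 doubles as a
known-groups variable and a change anchor, Item 2 as a (rejected) anchor
candidate. The 27 remaining items form six domains whose standardized
score is affine in the oriented raw sum: 0 at the worst achievable
response pattern, 100 at the best, linear in between. The three summaries
are unweighted means of domain scores, with sexual well-being optional in
GEN (and hence ALL): it is the most frequently unanswered scale and the
instrument's own guidance permits computing the general summaries without
it. Any other missing constituent makes the summary missing.

**Item map.** The instrument's item-level scoring manual is distributed
separately from the validation literature, so the default schema is a
reconstruction constrained by what the published arithmetic fixes exactly:
29 items total, 27 scored, and per-domain total raw ranges of 8 (FIS),
9 (FUN), 4 (SOC), 12 (SEX), 21 (FAT), and 42 (MDSS), which make each
domain's minimum possible change `100/range` reproduce the published row
{12.5, 11.1, 25.0, 4.8, 2.4} and make every tabulated group median an
achievable score. The SEX range of 12 is inferred from the granularity of
published medians (83, 67, 42, 17 are multiples of 100/12). Item counts
(4/3/2/4/7/7) and per-item level counts are choices within those
constraints; the schema is configuration-driven (YAML/JSON) and fully
swappable should the official map be available. Symptom-frequency domains
(FAT, MDSS) and the physical-limitation items are raw-coded higher =
worse and carry reversal flags, so the reversal logic is exercised by
default.

**Missing items.** A domain is scored when at least half its items are
answered (`min_answered_fraction = 0.5`, the common convention for
patient-reported outcomes; the validation literature is silent), with the
oriented sum prorated by the answered items' share of the raw range.
Scores stay at full float precision internally; one-decimal rounding is a
formatting concern.

## Synthetic cohort generator

The generator exists so every downstream stage is testable without the
sponsor-held trial data. It emulates the pooled four-trial design: per-
trial sizes 227/34/158/39, baseline and Week-24 visits everywhere, a
screening visit (14–35 days pre-baseline) only in the MEDALIST-like
trial, and no QLQ-C30 in the RevMDS-like trial.

Latent structure, per patient:

* a general HRQoL factor `g ~ N(0,1)` loading 0.6 on each domain trait
  (0.2 for SEX, which is deliberately weakly connected), giving moderate
  inter-domain correlations and weak SEX correlations;
* occasion latents `u_t = √ρ′·θ + √(1−ρ′)·ε_t` mixing the stable trait
  with fresh occasion noise;
* item responses as graded (cumulative-threshold) readouts
  `x_i = a·u_t + √(1−a²)·δ_i` with discrimination `a = 0.85` and a
  patient-persistent item residual `δ_i` (so a perfectly stable patient
  answers identically at screening and baseline), cut at thresholds set
  from per-domain marginal category probabilities;
* a shared Week-24 latent shift `Δ ~ N(drift_trial, 1)` loading ≈0.7 on
  each domain's change (0.15 for SEX) plus domain-specific change noise
  (SD 0.35); anchors, QLQ-C30 scales, and (weakly) hemoglobin and
  transfusion counts read the same latents with their own noise.

**Reliability calibration.** The ordinal readout attenuates latent
correlations while the persistent item residuals add a floor, so the
simulated test–retest ICC of a domain score is an approximately affine
function of the latent stability ρ′. Each domain stores a fitted
(intercept, slope) pair — estimated once from large-n simulations
(n = 5000, 8 seeds, two ρ′ grid points) — and the generator inverts it so
the realized ICC matches the configured `occasion_reliability`. Defaults
are the published per-domain ICCs (0.66/0.57/0.77/0.81/0.72/0.71);
realized values agree to within about 0.01 at large n.

**Distribution calibration.** Threshold probabilities were hand-tuned so
the pooled baseline means span the published band (lowest ≈47.5 at SOC,
highest ≈74 at FAT), SOC carries a heavy floor (~25% at 0), and FUN, SOC,
and SEX show >15% ceilings. Anchor loadings (0.93 for the two good
anchors, lower for the rest) put the change-score correlations of Item 1
and QLQ-C30 Item 29 in the 0.3–0.55 band on every non-SEX score while the
clinical anchors stay below 0.3, reproducing the published selection
outcome.

What the generator does **not** emulate: treatment arms and real
treatment effects, survival/progression, informative missingness (all
dropout is completely at random), visit-timing jitter, and the real
cohort's score dispersion — the synthetic baseline SDs (~24–37 points)
exceed the published ones (~14–21), so synthetic SEM/0.5·SD bounds and
hence some synthetic thresholds sit above the published values. Passing
the end-to-end tests therefore shows the machinery is correct under a
plausible data-generating process, not that real data would yield these
exact numbers.

## Analysis conventions

* **Quartiles** use linear interpolation between order statistics
  (`numpy.percentile` default); the published reports do not state their
  convention.
* **Decile bins** are half-open [x, x+10) with 100 its own category, so
  the ceiling cell is exact; floor/ceiling flags use a strict `> 15%` on
  non-missing denominators.
* **Spearman** correlations use average ranks for ties and the
  t-approximation on n−2 df for P values; pooled analyses stack baseline
  and Week-24 rows (up to two observations per patient). Fewer than three
  complete pairs yields a missing coefficient, not an error.
* **Magnitude bands**: |r| < 0.3 weak, < 0.7 moderate, < 0.9 strong,
  else very strong. A wrong-sign correlation with P > 0.05 is reported
  "indeterminate" rather than "wrong sign".
* **Known groups** compare medians and interquartile ranges; IQR overlap
  uses closed intervals (a shared endpoint counts as overlap, the
  conservative reading). Patients with missing baseline RBC units are
  excluded from the transfusion-dependence grouping.
* **ICC(A,1)** is computed from the two-way mean squares on listwise-
  complete subjects × occasions matrices, restricted to MEDALIST-like
  patients whose Item-1 rating was identical at screening and baseline.
  A constant matrix has no defined ICC (missing, with a warning).
* **Alpha/omega** use listwise deletion at the item-matrix level. Omega
  comes from a single-factor minimum-residual fit (least squares on the
  off-diagonal correlations, tolerance 1e-8, first principal axis as
  start); Heywood cases are clipped to zero uniqueness and flagged;
  two-item domains (SOC) cannot identify the model and report a missing
  omega. Sampling ICCs below 0 are clipped to 0 before entering SEM.

## Codified judgment calls in the MWPC procedure

Two steps of the published procedure are visual or verbal; the package
fixes them as deterministic rules.

**eCDF separation.** "Clearly and consistently separated" becomes: the
side group's eCDF lies strictly on the correct side of the no-change
eCDF at ≥80% of the pooled grid of observed change values, **and** the
between-group median difference is at least the score's minimum possible
change. Groups under three observations yield a missing verdict. A side
that fails contributes no anchor estimates to the triangulation (as
happened for FUN and SOC improvement in the published analysis).

**Threshold selection.** With D = max(SEM, 0.5·SD), the improvement
threshold is `floor(k*·mpc)` for the smallest positive integer k* with
`k*·mpc ≥ D − 0.5`; worsening is its negative. The half-point tolerance
absorbs the one-decimal rounding of printed inputs — it is required
because the published FIS threshold (12.5 → 12) sits 0.1 below its
printed SEM of 12.6. Applied to the published inputs this rule returns
exactly the published multiples (1× for FIS and SOC, 2× for FUN and FAT,
6× for MDSS). Summary scores have minimum steps below 0.1 points, which
carry no information, so they share a single common threshold: the floor
of the smallest primary-anchor mean improvement among GEN/ALL/TOI,
checked against each score's D (13 on the published inputs). A
consistency flag records whether each threshold falls within one point of
the eligible anchor-estimate range.

**Group collapsing** merges any anchor category with n ≤ 10 into its
neighbor toward "no change", outermost first, and never across the
no-change boundary; a side that cannot reach n > 10 is kept whole and
flagged rather than silently absorbed.

**Clinical anchor cut points.** The trial programme's Hb and RBC-unit
category definitions are not public; the defaults (±1.5 g/dL Hb change,
±2 RBC units, fewer units = improvement) are configuration placeholders,
not published values. They never matter for the shipped results because
these anchors fail the 0.3 eligibility rule.

## Problem sizes and tolerances in the test suite

Deterministic oracles run exactly (ICC vs a sums-of-squares ANOVA oracle
to 1e-10 on 100 random matrices; Spearman vs rank-then-Pearson to 1e-12;
closed-form alpha and omega). Stochastic checks use sizes chosen to keep
the default suite under a minute while leaving comfortable margins: ICC
parameter recovery uses 200 seeded cohorts of 260 MEDALIST-like patients
(120 stable retained), omega recovery n = 5000, distribution calibration
averages 20 default cohorts, and the end-to-end threshold-recovery
property runs 8 seeded full pipelines.

## Known limitations

* The default item map is a constrained reconstruction, not the official
  scoring manual; all published arithmetic it determines is exact, but
  item-level outputs (e.g. item-deleted alphas) refer to reconstructed
  items.
* No confidence intervals for ICC or thresholds (point estimates only,
  matching the published tables).
* The hypothesis grid ships as a sensible reconstruction and is meant to
  be edited; verdict logic, not the grid, is the tested computation.
* QLQ-C30 scale scores are consumed as given; the package does not score
  the QLQ-C30 from its items.
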