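# Methods

This package implements, end to end, the analysis behind a C-peptide-based
prediction model for type-2-diabetes (T2D) remission after metabolic
surgery, together with a synthetic-cohort generator that supplies data with
the statistical structure the analysis assumes. This note documents the
models, the numerical choices, and what the synthetic data do and do not
establish.

## Islet-function indexes (`t2drem.islet`)

From a three-point OGTT (glucose and C-peptide at 0/30/120 min), with
glucose in mmol/L and C-peptide in ng/mL:

* ΔC30 = CP30 − FCP, ΔC120 = CP120 − FCP (first-/second-phase secretion);
  negative increments are preserved — no clipping rule is part of the
  definitions.
* Insulinogenic indexes ΔC30/ΔG30 and ΔC120/ΔG120; a zero glucose
  increment is a degenerate denominator, reported as a missing value with
  a machine-readable reason so cohort pipelines stay total.
* HOMA-β(CP, DM) = 0.27 × FCP / (FPG − 3.5), in %, and
  HOMA-IR(CP) = 1.5 + FCP × FPG / 2800. The HOMA formulas were derived
  for C-peptide in pmol/L, while clinical tables usually report ng/mL; the
  two conventions differ by a factor of ≈331.1 and published cohort means
  are not reproducible from ng/mL inputs under the verbatim formulas. We
  therefore compute the formulas verbatim on the supplied values and
  expose a multiplicative `unit_factor` (default 1.0; documented
  alternative 331.1) instead of baking in a guess. With the default, the
  HOMA indexes are order-of-magnitude smaller than clinical-table values;
  all rank-based uses (median splits, ROC) are unaffected by the choice.
* C-peptide AUC = 0.25 × FCP + 4 × CP30 + 3 × CP120 — a fixed weighted
  sum, not a trapezoid over the 0/30/120 grid. The weights are part of the
  published definition and are implemented verbatim; their provenance is
  not documented anywhere we could verify, so no "corrected" trapezoid is
  offered.

`compute_all` never raises: each missing output carries a reason
(`missing_input` or `degenerate_denominator`). A vectorized counterpart
(`add_indices`) is the production path and is property-tested against the
scalar reference.

## Outcome classification (`t2drem.outcomes`)

Remission: HbA1c < 6.5 % **and** FPG < 7.1 mmol/L **and** no antidiabetic
medication (all bounds strict). Recurrence: FPG ≥ 7.0 mmol/L **or**
HbA1c ≥ 6.5 % **or** medication restart. The two FPG thresholds overlap on
[7.0, 7.1); we resolve this with an explicit precedence that implements
both definitions verbatim: remission eligibility uses < 7.1 for the
initial classification only, and once a remission is established the
recurrence bound ≥ 7.0 applies.

Windows are closed intervals of time since surgery: short term [1, 2]
years, long term [4, 6] years. A window with no evaluable visit is
*unevaluable* (loss to follow-up). Remission in a window requires every
evaluable in-window visit to qualify. Because the source cohort's visit
schedule is not documented, "sustained for at least one year" is
operationalized with a configurable single-visit policy:

* default (`allow_single_visit=True`): any qualifying visit attests
  remission, since every in-window time is ≥ 1 year after surgery;
* strict (`allow_single_visit=False`): the qualifying visits must span
  ≥ 1 year, or reach ≥ 1 year against the window end; otherwise the
  window is unevaluable (insufficient evidence is not non-remission).

Recurrence is assigned in the long window only when the short window
established remission — recurrence without prior remission is ordinary
non-remission. The record-level classifier is the reference; the
vectorized cohort classifier is the production path and is
property-tested against it.

## Scores (`t2drem.scores`)

**ACF** (the model under study): age < 40 y → 4 points, C-peptide
AUC > 30.93 ng/mL → 3, FPG < 7.0 mmol/L → 2; totals 0–9, with every
boundary value landing in the 0-point class exactly as defined. The
attainable totals are the subset sums of {4, 3, 2} = {0, 2, 3, 4, 5, 6,
7, 9}; 1 and 8 are unattainable and deliberately have no reporting band
(bands: 0, 2–5, 6–9).

**Comparators.** ABCD (0–10), DiaRem (0–22) and IMS bins are shipped as a
versioned YAML config (`data/score_bins.yaml`) rather than code, so they
remain auditable and overridable. ABCD and DiaRem are transcribed from
their original publications. The IMS nomogram's exact point values are
not available in an extractable form; the shipped IMS table is an
*approximate reconstruction* that preserves the published variable set,
monotone severity ordering, and the mild ≤ 25 / moderate (25, 95) /
severe ≥ 95 banding (boundary values 25 and 95 assigned to mild and
severe respectively, since the printed band labels are ambiguous there).
Analyses that use IMS only through its ordering and banding are
insensitive to the exact point values; absolute IMS point totals should
not be compared against other implementations.

Scoring a cohort applies listwise exclusion per system (patients lacking
the C-peptide AUC drop out of ACF only), with exclusion counts logged —
exclusions are data, not errors.

## Statistics (`t2drem.stats`)

* Chi-square (Pearson, continuity correction off by default,
  configurable), Welch t-test by default, Pearson correlation — all via
  scipy.
* The univariate screen dichotomizes islet-function indexes at the
  cohort median computed after listwise exclusion for that variable, uses
  the fixed clinical cutpoints for the other covariates, and flags
  predictors at p < 0.05 for the multivariable step.
* Logistic regression is maximum likelihood via Newton/IRLS
  (statsmodels), tolerance 1e-8, at most 25 iterations, Wald CIs.
  Separation is detected (solver signal, or any |coef| > 20 on the
  log-odds scale) and raised as an error: no estimates are reported for
  separated data.
* ROC: a subject is positive when score > threshold, over all distinct
  observed thresholds plus a sentinel that classifies everyone positive.
  The trapezoidal AUC equals the tie-corrected Mann–Whitney concordance
  (ties 1/2) — asserted against a brute-force oracle. For DiaRem and IMS
  (lower = better prognosis) a direction flag negates scores before the
  curve so higher always predicts remission.
* The Youden-optimal cutoff maximizes J = sens + spec − 1; ties (within
  1e-12, since J values are ratios of counts) break toward the lowest
  threshold for determinism.
* Paired AUC comparison uses DeLong's test on the structural components;
  a within-subject label-swap permutation test is available as a
  fallback. The source analysis did not name its AUC-comparison method;
  DeLong is the standard choice in this literature and the output labels
  the method used. Degenerate zero-variance comparisons return p = 1 for
  a zero difference and p = 0 otherwise.

## Synthetic cohorts (`t2drem.cohort`)

Only summary statistics of the source cohort are public, so the generator
reproduces *structure*, not patients:

* **Marginals.** Roughly symmetric covariates are truncated normals whose
  post-truncation moments equal the targets (the latent parameters are
  solved numerically; naive truncation would bias the SD). Right-skewed
  covariates (triglycerides, urinary microalbumin, C-peptide AUC; their
  reported means far exceed their medians) are moment-matched
  log-normals. Diabetes duration is a moment-matched scaled Beta on
  [0, 15] years: its target SD (4.8 y) exceeds what any truncated normal
  on that support can attain (the uniform limit is ≈4.3 y). Infeasible
  truncated-normal targets are rejected with a pointer to the Beta
  family rather than silently mis-calibrated.
* **Dependence** is a Gaussian copula. The reported duration–FCP and
  duration–C-peptide-AUC correlations (−0.257) are targeted on the
  latent scale (observed Pearson correlations attenuate slightly, to
  ≈−0.24/−0.20, well within the ±0.1 acceptance band); an FCP–C-peptide
  AUC correlation of 0.60 is added as a physiological-coherence choice
  (both measure residual β-cell function) — it is not a reported
  quantity. A jointly infeasible target matrix is repaired to the
  nearest PSD matrix with a warning.
* **OGTT construction.** The 30/120-min C-peptides are constructed so
  the weighted-sum AUC reproduces the latent C-peptide AUC exactly, with
  a random late-phase share of 45–70 % of the incremental response;
  glucose increments are positive draws so insulinogenic denominators
  are never degenerate. The 30-min C-peptide is then masked MCAR at the
  study's 5/87 rate, which removes ΔC30, ΔC30/ΔG30 and the C-peptide
  AUC downstream.
* **Outcomes.** Short-term remission follows a logistic model in the
  indicators age < 40 and C-peptide AUC > 30.93 with log-odds ln(7.705)
  and ln(4.530); long-term remission (among the ~57 % with long-term
  follow-up) uses C-peptide AUC and FPG < 7.0 with ln(8.139) and
  ln(4.517). Intercepts are not published; they are solved by root
  finding so the expected prevalence matches 60.92 % (short) and 38.00 %
  (long). Follow-up visits (three per window) are drawn consistent with
  the label, so the outcome classifier reproduces the generating labels
  exactly — tested as a round trip.
* **Known departures from the source data.** Short- and long-term
  outcomes are conditionally independent given the covariates, so
  recurrence after short-term remission is more frequent here than the
  5/53 observed; no surgical-procedure subgroups, weight-loss
  trajectories, or non-MCAR missingness are modelled. Passing tests on
  these cohorts demonstrate correctness of the *pipeline* under the
  assumed structure, not fidelity of the joint distribution, which is
  unknowable from published summaries.

`recover_parameters` is the validation harness: it re-derives outcomes
and the C-peptide AUC from the emitted tables and refits the generating
logistic model. At n = 5000, Wald 95 % CIs cover the generating log-odds
at the nominal rate (checked at ≥ 90 % over 100 replicates).

## Problem sizes and determinism

Simulation-based checks use n = 10 000 for moment/correlation convergence
(3-SE bands) and 100 replicates of n = 5000 for coverage; these sizes put
Monte-Carlo error well below the tolerances they are checked against.
Every stochastic component draws from a `numpy` Generator seeded
explicitly; identical seed and configuration reproduce every table
byte for byte (output paths are excluded from the config hash for this
reason).

## Limitations

* The HOMA unit convention is genuinely ambiguous in the source
  material; we default to formula-verbatim (ng/mL) and document the
  alternative rather than resolve it.
* IMS point values are reconstructed, not transcribed (see above).
* The published patient-level results (specific AUCs, fitted ORs) depend
  on the unavailable raw cohort; this package reproduces their
  *arithmetic* exactly and their *structure* on synthetic data, and makes
  no claim to reproduce the cohort-specific numbers.
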