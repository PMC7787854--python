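# t2drem

Prediction of type-2-diabetes (T2D) remission after metabolic surgery,
built around C-peptide-based islet-function indexes and a simple
three-variable risk score, for biostatisticians and clinical researchers
studying surgical T2D outcomes.

## The problem and the model

Metabolic surgery puts a substantial fraction of patients with T2D into
remission (HbA1c < 6.5 % and FPG < 7.1 mmol/L without antidiabetic
medication, sustained for at least a year), but candidates differ widely
in residual β-cell function, and East Asian cohorts in particular present
with lower BMI and worse islet function than the Western cohorts most
published scores were derived from. This package implements:

* **Islet-function indexes** from a 0/30/120-min OGTT, using C-peptide in
  place of insulin so the indexes survive exogenous insulin therapy:
  ΔC30, ΔC120, insulinogenic indexes ΔC/ΔG, HOMA-β(CP, DM), HOMA-IR(CP),
  and the weighted C-peptide AUC = 0.25·FCP + 4·CP30 + 3·CP120 (ng/mL).
* **Outcome classification** of follow-up visits into remission,
  non-remission and recurrence over short-term (1–2 y) and long-term
  (4–6 y) windows.
* **The ACF score** — Age < 40 y → 4 points, C-peptide AUC > 30.93
  ng/mL → 3, FPG < 7.0 mmol/L → 2; totals 0–9, higher = better remission
  prospects — plus the ABCD, DiaRem and IMS comparator scores (bin
  tables shipped as editable YAML config).
* **The statistical layer**: chi-square/t/Pearson, a univariate screen
  with median dichotomization of the indexes, Newton/IRLS logistic
  regression with Wald CIs and separation detection, ROC curves with the
  positive-if-score>threshold convention, Youden-optimal cutoffs, and
  DeLong paired AUC comparison.
* **A synthetic cohort generator** (Gaussian copula, moment-matched
  marginals, published effect sizes and prevalences) so the whole
  pipeline is testable without the unavailable clinical cohort.

## Worked example

Scoring one patient and reading a ROC cutoff:

```python
>>> from t2drem.islet import OgttRecord, cpeptide_auc
>>> from t2drem.scores import PatientBaseline, acf_score
>>> rec = OgttRecord(fpg=6.2, g30=10.1, g120=11.4, fcp=2.4, cp30=5.0, cp120=6.1)
>>> cpeptide_auc(rec)
38.9
>>> res = acf_score(PatientBaseline(age=37, cpeptide_auc=38.9, fpg=6.2))
>>> res.points, res.band, res.components
(9, '6-9', {'age': 4, 'cpeptide_auc': 3, 'fpg': 2})
```

This patient is young, keeps a stimulated C-peptide response above the
30.93 ng/mL cutoff, and has fasting glucose below 7.0 mmol/L, so every
component fires and the score reaches its maximum of 9 — the most
favourable remission prognosis the scale expresses.

The full analysis is a sequence of thin drivers over the library
(equivalently: `t2drem run-all --seed 20201031`):

```sh
python analysis/01_simulate_cohort.py   # 87-patient synthetic cohort
python analysis/02_islet_indices.py    # OGTT-derived indexes
python analysis/03_classify_outcomes.py
python analysis/04_score_patients.py   # ACF + comparators, band counts
python analysis/05_statistics.py       # screen, logistic, ROC, DeLong
```

On the default seed the drivers print, among other things:

```
short-term: 53/87 in remission (60.92%); breakdown {'remission': 53, 'non_remission': 34}
...
ACF     n=82  band distribution: {'0': 19, '2-5': 43, '6-9': 20}
...
score AUCs vs ACF (DeLong):
window system   auc  n  auc_diff_vs_acf  p_vs_acf comparison_method
 short    ACF 0.760 82              NaN       NaN               NaN
 short   ABCD 0.591 82            0.169  0.032199            delong
```

i.e. five patients lack the 30-min C-peptide sample (so 82 are ACF-
scorable), 60.92 % of the simulated cohort remits short term, and on this
draw the ACF score separates remitters from non-remitters better than
the comparators — the structural behaviour the score was designed for.
Report tables (univariate screen, logistic ORs, ROC/Youden summary,
per-band remission rates, AUC comparisons) land under `results/` as CSV
plus a machine-readable `summary.json`.

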