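#!/usr/bin/env python
"""Score every patient under ACF, ABCD, DiaRem and IMS.

The ACF score (0–9; age < 40 → 4, C-peptide AUC > 30.93 ng/mL → 3,
FPG < 7.0 mmol/L → 2) is computed alongside the three previously
published comparators; patients lacking a system's inputs (notably the
C-peptide AUC for ACF) are excluded from that system only.

Reads results/cohort/ and results/indices.csv, writes results/scores.csv.
"""

import argparse

import pandas as pd

from t2drem.pipeline import read_cohort
from t2drem.scores import score_cohort


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", default="results/cohort")
    ap.add_argument("--indices", default="results/indices.csv")
    ap.add_argument("--out", default="results/scores.csv")
    args = ap.parse_args()

    cohort, _ = read_cohort(args.cohort)
    indices = pd.read_csv(args.indices, comment="#")
    merged = cohort.baseline.merge(indices, on="patient_id", how="left")
    table = score_cohort(merged)
    table.to_csv(args.out, index=False)

    print(f"{len(table)} score rows -> {args.out}")
    for system, g in table.groupby("system"):
        dist = g["band"].value_counts().sort_index().to_dict()
        print(f"{system:<7} n={len(g):<3} band distribution: {dist}")


if __name__ == "__main__":
    main()
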