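#!/usr/bin/env python
"""Derive the eight C-peptide-based islet-function indexes for the cohort.

Appends ΔC30, ΔC120, the insulinogenic indexes, HOMA-β(CP), HOMA-IR(CP)
and the weighted C-peptide AUC to the OGTT table and summarizes them,
including the correlation of each with diabetes duration (longer disease
course should show weaker residual β-cell function).

Reads results/cohort/, writes results/indices.csv.
"""

import argparse

from t2drem import islet, stats
from t2drem.pipeline import read_cohort


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", default="results/cohort")
    ap.add_argument("--out", default="results/indices.csv")
    ap.add_argument("--unit-factor", type=float, default=1.0)
    args = ap.parse_args()

    cohort, _ = read_cohort(args.cohort)
    indices = islet.add_indices(cohort.ogtt, unit_factor=args.unit_factor)
    indices.to_csv(args.out, index=False)

    merged = cohort.baseline.merge(indices, on="patient_id")
    print(f"indexes for {len(indices)} patients -> {args.out}")
    print(f"{'index':<14}{'mean':>8}{'sd':>8}{'r(duration)':>14}{'p':>9}")
    for col in ("fcp",) + islet.INDEX_COLUMNS:
        sub = merged[["duration", col]].dropna()
        r, p = stats.pearson_r(sub["duration"], sub[col])
        print(
            f"{col:<14}{merged[col].mean():>8.2f}{merged[col].std():>8.2f}"
            f"{r:>14.3f}{p:>9.3f}"
        )


if __name__ == "__main__":
    main()
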