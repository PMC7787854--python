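#!/usr/bin/env python
"""Classify follow-up visits into remission / non-remission / recurrence.

Applies the remission criteria (HbA1c < 6.5 %, FPG < 7.1 mmol/L, off
medication) over the short-term [1, 2] y and long-term [4, 6] y windows,
with recurrence (FPG >= 7.0, HbA1c >= 6.5 or medication restart) only
after an established remission.

Reads results/cohort/, writes results/outcomes.csv.
"""

import argparse

from t2drem.outcomes import classify_cohort
from t2drem.pipeline import read_cohort


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", default="results/cohort")
    ap.add_argument("--out", default="results/outcomes.csv")
    args = ap.parse_args()

    cohort, _ = read_cohort(args.cohort)
    labels = classify_cohort(cohort.followup)
    labels.to_csv(args.out, index=False)

    for window in ("short", "long"):
        col = f"{window}_term_status"
        counts = labels[col].value_counts().to_dict()
        evaluable = sum(v for k, v in counts.items() if k != "unevaluable")
        n_rem = counts.get("remission", 0)
        pct = 100.0 * n_rem / evaluable if evaluable else float("nan")
        print(
            f"{window}-term: {n_rem}/{evaluable} in remission ({pct:.2f}%); "
            f"breakdown {counts}"
        )
    n_rec = int((labels["long_term_status"] == "recurrence").sum())
    print(f"{n_rec} patients relapsed after an initial short-term remission")


if __name__ == "__main__":
    main()
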