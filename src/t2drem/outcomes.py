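"""Postsurgery remission, non-remission, and recurrence classification.

Remission requires HbA1c < 6.5 % and FPG < 7.1 mmol/L off antidiabetic
medication; recurrence is a return to the diabetic range (FPG ≥ 7.0 mmol/L
or HbA1c ≥ 6.5 %) or medication restart after an established remission.
The two FPG thresholds overlap as defined (7.0 vs 7.1): remission
eligibility uses < 7.1 only for the initial classification, and once
remission is established recurrence uses ≥ 7.0.

Outcomes are evaluated inside two closed windows of time since surgery:
short term [1, 2] years and long term [4, 6] years. A window with no visit
is unevaluable (loss to follow-up).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FollowUpRecord",
    "OutcomeLabel",
    "Window",
    "Status",
    "UnevaluableVisitError",
    "visit_meets_remission",
    "visit_meets_recurrence",
    "classify_patient",
    "classify_cohort",
    "REMISSION_HBA1C",
    "REMISSION_FPG",
    "RECURRENCE_FPG",
    "RECURRENCE_HBA1C",
    "SHORT_WINDOW",
    "LONG_WINDOW",
]

REMISSION_HBA1C = 6.5  # %, strict upper bound
REMISSION_FPG = 7.1  # mmol/L, strict upper bound
RECURRENCE_HBA1C = 6.5  # %, inclusive lower bound
RECURRENCE_FPG = 7.0  # mmol/L, inclusive lower bound

SHORT_WINDOW = (1.0, 2.0)  # years since surgery, closed interval
LONG_WINDOW = (4.0, 6.0)


class Window(str, Enum):
    SHORT_TERM = "short_term"
    LONG_TERM = "long_term"
    OUTSIDE = "outside"


class Status(str, Enum):
    REMISSION = "remission"
    NON_REMISSION = "non_remission"
    RECURRENCE = "recurrence"
    UNEVALUABLE = "unevaluable"


class UnevaluableVisitError(ValueError):
    """A visit lacks the fields needed to apply the outcome criteria."""


def _missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


@dataclass(frozen=True)
class FollowUpRecord:
    """One postsurgery visit: time since surgery (years), HbA1c (%),
    FPG (mmol/L), and whether the patient is on antidiabetic medication."""

    t: float
    hba1c: float | None = None
    fpg: float | None = None
    on_antidiabetic_medication: bool | None = None

    def __post_init__(self) -> None:
        if _missing(self.t) or not math.isfinite(self.t) or self.t <= 0:
            raise ValueError(f"t={self.t!r}: time since surgery must be finite and > 0")
        for name in ("hba1c", "fpg"):
            v = getattr(self, name)
            if _missing(v):
                object.__setattr__(self, name, None)
            elif not math.isfinite(float(v)) or v < 0:
                raise ValueError(f"{name}={v!r}: must be finite and >= 0")
        if _missing(self.on_antidiabetic_medication):
            object.__setattr__(self, "on_antidiabetic_medication", None)


@dataclass(frozen=True)
class OutcomeLabel:
    window: Window
    status: Status


def _check_complete(v: FollowUpRecord) -> None:
    for name in ("hba1c", "fpg", "on_antidiabetic_medication"):
        if getattr(v, name) is None:
            raise UnevaluableVisitError(f"visit at t={v.t}: {name} missing")


def visit_meets_remission(v: FollowUpRecord) -> bool:
    """True iff HbA1c < 6.5, FPG < 7.1 and off medication (strict bounds)."""
    _check_complete(v)
    return (
        v.hba1c < REMISSION_HBA1C
        and v.fpg < REMISSION_FPG
        and not v.on_antidiabetic_medication
    )


def visit_meets_recurrence(v: FollowUpRecord) -> bool:
    """True iff FPG ≥ 7.0 or HbA1c ≥ 6.5 or on antidiabetic medication.

    Only meaningful after an established remission (see module docstring).
    """
    _check_complete(v)
    return (
        v.fpg >= RECURRENCE_FPG
        or v.hba1c >= RECURRENCE_HBA1C
        or bool(v.on_antidiabetic_medication)
    )


def _window_status(
    visits: Sequence[FollowUpRecord],
    window: tuple[float, float],
    prior_remission: bool,
    allow_single_visit: bool,
) -> Status:
    lo, hi = window
    in_window = [v for v in visits if lo <= v.t <= hi]
    evaluable = [
        v
        for v in in_window
        if v.hba1c is not None
        and v.fpg is not None
        and v.on_antidiabetic_medication is not None
    ]
    if not evaluable:
        return Status.UNEVALUABLE
    if all(visit_meets_remission(v) for v in evaluable):
        if allow_single_visit:
            # window start >= 1 year, so any qualifying visit attests
            # at least one year of remission
            return Status.REMISSION
        ts = [v.t for v in evaluable]
        sustained = (max(ts) - min(ts) >= 1.0) or (hi - min(ts) >= 1.0)
        return Status.REMISSION if sustained else Status.UNEVALUABLE
    if prior_remission and any(visit_meets_recurrence(v) for v in evaluable):
        return Status.RECURRENCE
    return Status.NON_REMISSION


def classify_patient(
    visits: Iterable[FollowUpRecord],
    *,
    short_window: tuple[float, float] = SHORT_WINDOW,
    long_window: tuple[float, float] = LONG_WINDOW,
    allow_single_visit: bool = True,
) -> tuple[OutcomeLabel, OutcomeLabel]:
    """Assign short- and long-term outcome labels from a visit history.

    Remission in a window requires every evaluable in-window visit to meet
    the remission criteria; with ``allow_single_visit=False`` the qualifying
    visits must additionally span (or reach, against the window end) at
    least one year. Recurrence is assigned in the long window only when the
    short window established remission. Windows with no evaluable visit are
    unevaluable.

    ``visits`` are sorted by time internally, so already-sorted input and
    duplicated identical visits do not change the result.
    """
    vs = sorted(visits, key=lambda v: v.t)
    short = _window_status(vs, short_window, False, allow_single_visit)
    long = _window_status(
        vs, long_window, prior_remission=(short is Status.REMISSION),
        allow_single_visit=allow_single_visit,
    )
    return (
        OutcomeLabel(Window.SHORT_TERM, short),
        OutcomeLabel(Window.LONG_TERM, long),
    )


def classify_cohort(
    followup: pd.DataFrame,
    *,
    short_window: tuple[float, float] = SHORT_WINDOW,
    long_window: tuple[float, float] = LONG_WINDOW,
    allow_single_visit: bool = True,
) -> pd.DataFrame:
    """Vectorized cohort classification.

    ``followup`` columns: patient_id, t_years, hba1c, fpg, on_meds.
    Returns one row per patient: patient_id, short_term_status,
    long_term_status. Agrees with :func:`classify_patient` per patient
    (property-tested).
    """
    req = ["patient_id", "t_years", "hba1c", "fpg", "on_meds"]
    absent = [c for c in req if c not in followup.columns]
    if absent:
        raise KeyError(f"follow-up table lacks columns: {absent}")
    df = followup.copy()
    if df.empty:
        return pd.DataFrame(
            columns=["patient_id", "short_term_status", "long_term_status"]
        )
    t = df["t_years"].astype(float)
    hba1c = df["hba1c"].astype(float)
    fpg = df["fpg"].astype(float)
    meds_raw = df["on_meds"]
    meds_missing = meds_raw.isna()
    meds = meds_raw.fillna(False).astype(bool)
    evaluable = hba1c.notna() & fpg.notna() & ~meds_missing

    remit = (hba1c < REMISSION_HBA1C) & (fpg < REMISSION_FPG) & ~meds
    recur = (fpg >= RECURRENCE_FPG) | (hba1c >= RECURRENCE_HBA1C) | meds

    out_parts = {}
    for name, (lo, hi) in (("short", short_window), ("long", long_window)):
        inw = (t >= lo) & (t <= hi) & evaluable
        agg = pd.DataFrame(
            {
                "patient_id": df["patient_id"],
                "n_eval": inw.astype(int),
                "all_remit": np.where(inw, remit, True),
                "any_recur": np.where(inw, recur, False),
                "t_min": np.where(inw, t, np.inf),
                "t_max": np.where(inw, t, -np.inf),
            }
        ).groupby("patient_id", sort=True).agg(
            n_eval=("n_eval", "sum"),
            all_remit=("all_remit", "min"),
            any_recur=("any_recur", "max"),
            t_min=("t_min", "min"),
            t_max=("t_max", "max"),
        )
        if not allow_single_visit:
            sustained = (agg["t_max"] - agg["t_min"] >= 1.0) | (
                hi - agg["t_min"] >= 1.0
            )
        else:
            sustained = pd.Series(True, index=agg.index)
        out_parts[name] = agg.assign(sustained=sustained)

    short = out_parts["short"]
    short_status = np.select(
        [
            short["n_eval"] == 0,
            short["all_remit"].astype(bool) & short["sustained"],
            short["all_remit"].astype(bool) & ~short["sustained"],
        ],
        [Status.UNEVALUABLE.value, Status.REMISSION.value, Status.UNEVALUABLE.value],
        default=Status.NON_REMISSION.value,
    )
    prior = pd.Series(short_status == Status.REMISSION.value, index=short.index)

    long = out_parts["long"].reindex(short.index)
    long_remit = long["all_remit"].astype(bool)
    long_status = np.select(
        [
            long["n_eval"] == 0,
            long_remit & long["sustained"],
            long_remit & ~long["sustained"],
            ~long_remit & prior & long["any_recur"].astype(bool),
        ],
        [
            Status.UNEVALUABLE.value,
            Status.REMISSION.value,
            Status.UNEVALUABLE.value,
            Status.RECURRENCE.value,
        ],
        default=Status.NON_REMISSION.value,
    )
    return pd.DataFrame(
        {
            "patient_id": short.index,
            "short_term_status": short_status,
            "long_term_status": long_status,
        }
    ).reset_index(drop=True)
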