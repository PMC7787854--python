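"""Remission-prediction scores: ACF and the ABCD / DiaRem / IMS comparators.

The ACF score grades three presurgery variables — Age (< 40 yr: 4 points),
C-peptide AUC (> 30.93 ng/mL: 3 points), FPG (< 7.0 mmol/L: 2 points) — for
a total of 0–9; higher totals predict a better chance of type-2-diabetes
remission after metabolic surgery. Boundary values land in the 0-point
class (age 40, C-peptide AUC 30.93, FPG 7.0 score nothing). The attainable
totals are the subset sums of {4, 3, 2}: {0, 2, 3, 4, 5, 6, 7, 9}; 1 and 8
cannot occur and have no band.

The comparator systems' bin boundaries are data, not code: they live in a
versioned YAML config shipped with the package (``data/score_bins.yaml``)
so they stay auditable and overridable. Higher ABCD (0–10) and ACF predict
remission; lower DiaRem (0–22) and IMS predict remission.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Iterable, Mapping

import pandas as pd
import yaml

__all__ = [
    "PatientBaseline",
    "ScoreResult",
    "MissingScoreInputError",
    "acf_score",
    "acf_band",
    "abcd_score",
    "diarem_score",
    "ims_score",
    "score_cohort",
    "load_score_config",
    "ACF_AGE_CUTOFF",
    "ACF_CPAUC_CUTOFF",
    "ACF_FPG_CUTOFF",
    "ACF_ATTAINABLE_TOTALS",
    "SYSTEMS",
]

logger = logging.getLogger(__name__)

ACF_AGE_CUTOFF = 40.0  # years
ACF_CPAUC_CUTOFF = 30.93  # ng/mL
ACF_FPG_CUTOFF = 7.0  # mmol/L
ACF_POINTS = {"age": 4, "cpeptide_auc": 3, "fpg": 2}
#: subset sums of {4, 3, 2}
ACF_ATTAINABLE_TOTALS = frozenset({0, 2, 3, 4, 5, 6, 7, 9})

SYSTEMS = ("ACF", "ABCD", "DiaRem", "IMS")


class MissingScoreInputError(ValueError):
    """A variable required by the scoring system is absent; no imputation."""


class ScoreConfigError(ValueError):
    """The score-bin config is malformed."""


def _missing(v) -> bool:
    if v is None:
        return True
    try:
        return math.isnan(float(v))
    except (TypeError, ValueError):
        return False


@dataclass(frozen=True)
class PatientBaseline:
    """Presurgery covariates consumed by the four scoring systems.

    With ``validate=True`` the study's inclusion criteria are enforced
    (age 18–70 years, diabetes duration <= 15 years).
    """

    age: float | None = None
    sex: str | None = None
    bmi: float | None = None
    duration: float | None = None
    fpg: float | None = None
    hba1c: float | None = None
    fcp: float | None = None
    cpeptide_auc: float | None = None
    n_diabetes_medications: int | None = None
    insulin_use: bool | None = None
    other_antidiabetic_drug_use: bool | None = None
    validate: bool = False

    def __post_init__(self) -> None:
        if self.validate:
            if not _missing(self.age) and not (18 <= self.age <= 70):
                raise ValueError(f"age={self.age}: inclusion range is 18-70 years")
            if not _missing(self.duration) and not (0 <= self.duration <= 15):
                raise ValueError(
                    f"duration={self.duration}: inclusion limit is 15 years"
                )
        if self.n_diabetes_medications is not None and not _missing(
            self.n_diabetes_medications
        ):
            if self.n_diabetes_medications < 0:
                raise ValueError("n_diabetes_medications must be >= 0")


@dataclass(frozen=True)
class ScoreResult:
    system: str
    points: float
    band: str
    components: dict[str, float] = field(default_factory=dict)


def _require(p: PatientBaseline, names: Iterable[str], system: str) -> dict[str, Any]:
    vals = {}
    for n in names:
        v = getattr(p, n)
        if _missing(v):
            raise MissingScoreInputError(f"{system}: required input {n!r} is missing")
        vals[n] = v
    return vals


def acf_band(points: int) -> str:
    """Reporting band of an attainable ACF total: '0', '2-5' or '6-9'."""
    if points not in ACF_ATTAINABLE_TOTALS:
        raise ValueError(f"ACF total {points} is not attainable and has no band")
    if points == 0:
        return "0"
    return "2-5" if points <= 5 else "6-9"


def acf_score(p: PatientBaseline) -> ScoreResult:
    """ACF score: age < 40 → 4, C-peptide AUC > 30.93 → 3, FPG < 7.0 → 2."""
    v = _require(p, ("age", "cpeptide_auc", "fpg"), "ACF")
    components = {
        "age": ACF_POINTS["age"] if v["age"] < ACF_AGE_CUTOFF else 0,
        "cpeptide_auc": (
            ACF_POINTS["cpeptide_auc"] if v["cpeptide_auc"] > ACF_CPAUC_CUTOFF else 0
        ),
        "fpg": ACF_POINTS["fpg"] if v["fpg"] < ACF_FPG_CUTOFF else 0,
    }
    total = sum(components.values())
    return ScoreResult("ACF", total, acf_band(total), components)


_CONFIG_CACHE: dict[str, Any] | None = None


def load_score_config(path: str | None = None) -> dict[str, Any]:
    """Load the comparator bin tables (package default or an override file)."""
    global _CONFIG_CACHE
    if path is None:
        if _CONFIG_CACHE is None:
            text = (
                resources.files("t2drem.data").joinpath("score_bins.yaml").read_text()
            )
            _CONFIG_CACHE = yaml.safe_load(text)
        return _CONFIG_CACHE
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def _points_from_rules(value: float, rules: list[dict]) -> float:
    for r in rules:
        if "max" not in r:
            return float(r["points"])
        hit = value <= r["max"] if r.get("inclusive") else value < r["max"]
        if hit:
            return float(r["points"])
    raise ScoreConfigError("rule list has no terminal rule")


def _component_points(
    system_cfg: Mapping[str, Any], values: Mapping[str, Any], system: str
) -> dict[str, float]:
    comps = {}
    for var, spec in system_cfg["variables"].items():
        v = values[var]
        if "flag_points" in spec:
            comps[var] = float(spec["flag_points"]) if v else 0.0
        else:
            comps[var] = _points_from_rules(float(v), spec["rules"])
    return comps


def _range_band(points: float, bands: Mapping[str, list]) -> str:
    for label, (lo, hi) in bands.items():
        if lo <= points <= hi:
            return label
    raise ValueError(f"total {points} falls in no configured band")


def abcd_score(p: PatientBaseline, config: Mapping | None = None) -> ScoreResult:
    """ABCD score (0–10) from age, BMI, fasting C-peptide and T2D duration."""
    cfg = (config or load_score_config())["abcd"]
    v = _require(p, ("age", "bmi", "fcp", "duration"), "ABCD")
    comps = _component_points(cfg, v, "ABCD")
    total = sum(comps.values())
    return ScoreResult("ABCD", total, _range_band(total, cfg["bands"]), comps)


def diarem_score(p: PatientBaseline, config: Mapping | None = None) -> ScoreResult:
    """DiaRem score (0–22) from age, HbA1c, drug use and insulin use."""
    cfg = (config or load_score_config())["diarem"]
    v = _require(
        p, ("age", "hba1c", "other_antidiabetic_drug_use", "insulin_use"), "DiaRem"
    )
    comps = _component_points(cfg, v, "DiaRem")
    total = sum(comps.values())
    return ScoreResult("DiaRem", total, _range_band(total, cfg["bands"]), comps)


def ims_score(p: PatientBaseline, config: Mapping | None = None) -> ScoreResult:
    """IMS score from medication count, insulin use, duration and HbA1c.

    Banded into diabetes-severity classes: mild (<= 25), moderate (25–95),
    severe (>= 95); exact boundary values 25 and 95 fall to mild and severe
    respectively.
    """
    cfg = (config or load_score_config())["ims"]
    v = _require(
        p, ("n_diabetes_medications", "insulin_use", "duration", "hba1c"), "IMS"
    )
    comps = _component_points(cfg, v, "IMS")
    total = sum(comps.values())
    bands = cfg["bands"]
    if total <= bands["mild_max"]:
        band = "mild"
    elif total >= bands["severe_min"]:
        band = "severe"
    else:
        band = "moderate"
    return ScoreResult("IMS", total, band, comps)


_SCORERS = {
    "ACF": acf_score,
    "ABCD": abcd_score,
    "DiaRem": diarem_score,
    "IMS": ims_score,
}


def score_cohort(
    patients: pd.DataFrame,
    systems: Iterable[str] = SYSTEMS,
    config: Mapping | None = None,
) -> pd.DataFrame:
    """Score every patient under every requested system.

    ``patients`` carries one row per patient with the PatientBaseline
    columns plus patient_id. Patients lacking a system's inputs are
    excluded from that system (listwise), with exclusion counts logged;
    exclusions are data, not errors.

    Returns a long table: patient_id, system, points, band, and one
    ``comp_<variable>`` column per scoring component.
    """
    rows = []
    excluded: dict[str, int] = {s: 0 for s in systems}
    baseline_fields = [
        "age", "sex", "bmi", "duration", "fpg", "hba1c", "fcp",
        "cpeptide_auc", "n_diabetes_medications", "insulin_use",
        "other_antidiabetic_drug_use",
    ]
    for _, r in patients.iterrows():
        p = PatientBaseline(
            **{f: r.get(f) for f in baseline_fields if f in patients.columns}
        )
        for system in systems:
            kwargs = {} if system == "ACF" else {"config": config}
            try:
                res = _SCORERS[system](p, **kwargs)
            except MissingScoreInputError:
                excluded[system] += 1
                continue
            row = {
                "patient_id": r.get("patient_id"),
                "system": system,
                "points": res.points,
                "band": res.band,
            }
            row.update({f"comp_{k}": v for k, v in res.components.items()})
            rows.append(row)
    for system, n in excluded.items():
        if n:
            logger.info("%s: %d patients excluded for missing inputs", system, n)
    cols = ["patient_id", "system", "points", "band"]
    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(columns=cols)
    return out
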