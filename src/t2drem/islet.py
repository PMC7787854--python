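"""Islet-function indexes from a three-point (0/30/120 min) OGTT.

β-cell function and insulin resistance are summarized from glucose and
C-peptide sampled fasting and at 30 and 120 minutes of an oral glucose
tolerance test. C-peptide stands in for insulin throughout, so the indexes
stay interpretable in patients treated with exogenous insulin.

Units: glucose in mmol/L, C-peptide in ng/mL. The HOMA formulas were
originally derived for C-peptide in pmol/L; a multiplicative ``unit_factor``
(default 1.0, i.e. the value is used as supplied; 331.1 converts ng/mL to
pmol/L) makes the convention explicit instead of baking in a guess.

The C-peptide AUC used here is the fixed weighted sum
``0.25*FCP + 4*CP30 + 3*CP120`` (not a trapezoid over the time grid).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

__all__ = [
    "OgttRecord",
    "IsletIndices",
    "MissingInputError",
    "DegenerateDenominatorError",
    "IsletDomainWarning",
    "delta_c30",
    "delta_c120",
    "insulinogenic_30",
    "insulinogenic_120",
    "homa_beta_cp",
    "homa_ir_cp",
    "cpeptide_auc",
    "compute_all",
    "add_indices",
    "INDEX_COLUMNS",
]

#: columns appended to a cohort table by :func:`add_indices`
INDEX_COLUMNS = (
    "delta_c30",
    "delta_c120",
    "ii30",
    "ii120",
    "homa_beta_cp",
    "homa_ir_cp",
    "cpeptide_auc",
)

# machine-readable reasons attached to missing outputs
MISSING_INPUT = "missing_input"
DEGENERATE_DENOMINATOR = "degenerate_denominator"

HOMA_BETA_GLUCOSE_OFFSET = 3.5  # mmol/L, HOMA-β denominator offset
HOMA_IR_FLOOR = 1.5  # additive floor of the C-peptide HOMA-IR
HOMA_IR_SCALE = 2800.0

#: documented conversion, pmol/L per ng/mL of C-peptide
NGML_TO_PMOLL = 331.1


class MissingInputError(ValueError):
    """A required OGTT field is absent."""


class DegenerateDenominatorError(ZeroDivisionError):
    """A ratio index has a zero denominator (e.g. no glucose increment)."""


class IsletDomainWarning(UserWarning):
    """The inputs are outside the range the formula was derived for."""


def _missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


@dataclass(frozen=True)
class OgttRecord:
    """One patient's OGTT measurements; any field may be missing (None/NaN).

    fpg, g30, g120
        plasma glucose at 0/30/120 min (mmol/L)
    fcp, cp30, cp120
        C-peptide at 0/30/120 min (ng/mL)
    """

    fpg: float | None = None
    g30: float | None = None
    g120: float | None = None
    fcp: float | None = None
    cp30: float | None = None
    cp120: float | None = None

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if _missing(v):
                object.__setattr__(self, f.name, None)
                continue
            v = float(v)
            if not math.isfinite(v) or v < 0:
                raise ValueError(
                    f"{f.name}={v!r}: concentrations must be finite and >= 0"
                )
            object.__setattr__(self, f.name, v)


def _require(rec: OgttRecord, *names: str) -> list[float]:
    vals = []
    for n in names:
        v = getattr(rec, n)
        if _missing(v):
            raise MissingInputError(f"field {n!r} is missing")
        vals.append(v)
    return vals


def delta_c30(rec: OgttRecord) -> float:
    """First-phase C-peptide increment ΔC30 = CP30 − FCP (ng/mL).

    Negative increments are preserved as computed.
    """
    cp30, fcp = _require(rec, "cp30", "fcp")
    return cp30 - fcp


def delta_c120(rec: OgttRecord) -> float:
    """Second-phase C-peptide increment ΔC120 = CP120 − FCP (ng/mL)."""
    cp120, fcp = _require(rec, "cp120", "fcp")
    return cp120 - fcp


def insulinogenic_30(rec: OgttRecord) -> float:
    """30-min insulinogenic index ΔC30/ΔG30 (μg/mmol)."""
    fpg, g30 = _require(rec, "fpg", "g30")
    num = delta_c30(rec)
    if g30 == fpg:
        raise DegenerateDenominatorError("g30 == fpg: zero glucose increment")
    return num / (g30 - fpg)


def insulinogenic_120(rec: OgttRecord) -> float:
    """120-min insulinogenic index ΔC120/ΔG120 (μg/mmol)."""
    fpg, g120 = _require(rec, "fpg", "g120")
    num = delta_c120(rec)
    if g120 == fpg:
        raise DegenerateDenominatorError("g120 == fpg: zero glucose increment")
    return num / (g120 - fpg)


def homa_beta_cp(rec: OgttRecord, unit_factor: float = 1.0) -> float:
    """C-peptide HOMA-β for diabetic range: 0.27 × FCP / (FPG − 3.5), in %.

    ``unit_factor`` rescales FCP before the formula (1.0 = use as supplied;
    :data:`NGML_TO_PMOLL` for the pmol/L convention). A warning is issued for
    FPG below 3.5 mmol/L, where the formula's denominator changes sign; the
    (negative) value is preserved.
    """
    fcp, fpg = _require(rec, "fcp", "fpg")
    if fpg == HOMA_BETA_GLUCOSE_OFFSET:
        raise DegenerateDenominatorError("fpg == 3.5: HOMA-β undefined")
    if fpg < HOMA_BETA_GLUCOSE_OFFSET:
        warnings.warn(
            f"fpg={fpg} < 3.5 mmol/L: HOMA-β outside its derivation range",
            IsletDomainWarning,
            stacklevel=2,
        )
    return 0.27 * (fcp * unit_factor) / (fpg - HOMA_BETA_GLUCOSE_OFFSET)


def homa_ir_cp(rec: OgttRecord, unit_factor: float = 1.0) -> float:
    """C-peptide HOMA-IR: 1.5 + FCP × FPG / 2800 (dimensionless).

    The additive constant puts a floor of 1.5 on the index for any
    nonnegative inputs.
    """
    fcp, fpg = _require(rec, "fcp", "fpg")
    return HOMA_IR_FLOOR + (fcp * unit_factor) * fpg / HOMA_IR_SCALE


def cpeptide_auc(rec: OgttRecord) -> float:
    """Weighted C-peptide response: 0.25×FCP + 4×CP30 + 3×CP120 (ng/mL)."""
    fcp, cp30, cp120 = _require(rec, "fcp", "cp30", "cp120")
    return 0.25 * fcp + 4.0 * cp30 + 3.0 * cp120


@dataclass(frozen=True)
class IsletIndices:
    """All derivable indexes for one record; NaN marks a missing value.

    ``missing`` maps each absent field to a machine-readable reason
    (``missing_input`` or ``degenerate_denominator``).
    """

    fcp: float = math.nan
    delta_c30: float = math.nan
    delta_c120: float = math.nan
    ii30: float = math.nan
    ii120: float = math.nan
    homa_beta_cp: float = math.nan
    homa_ir_cp: float = math.nan
    cpeptide_auc: float = math.nan
    missing: dict[str, str] = field(default_factory=dict)


def compute_all(rec: OgttRecord, unit_factor: float = 1.0) -> IsletIndices:
    """Compute every derivable index; never raises.

    Fields whose inputs are absent, or whose denominator is degenerate,
    come back as NaN with a reason in ``missing``.
    """
    ops = {
        "delta_c30": delta_c30,
        "delta_c120": delta_c120,
        "ii30": insulinogenic_30,
        "ii120": insulinogenic_120,
        "homa_beta_cp": lambda r: homa_beta_cp(r, unit_factor),
        "homa_ir_cp": lambda r: homa_ir_cp(r, unit_factor),
        "cpeptide_auc": cpeptide_auc,
    }
    values: dict[str, float] = {}
    reasons: dict[str, str] = {}
    if _missing(rec.fcp):
        reasons["fcp"] = MISSING_INPUT
    else:
        values["fcp"] = rec.fcp
    for name, op in ops.items():
        try:
            values[name] = op(rec)
        except MissingInputError:
            reasons[name] = MISSING_INPUT
        except DegenerateDenominatorError:
            reasons[name] = DEGENERATE_DENOMINATOR
    return IsletIndices(missing=reasons, **values)


def add_indices(df: pd.DataFrame, unit_factor: float = 1.0) -> pd.DataFrame:
    """Append the index columns to a cohort table (vectorized).

    ``df`` must carry the OGTT columns fpg, g30, g120, fcp, cp30, cp120;
    NaN inputs propagate to NaN outputs, degenerate denominators give NaN.
    Returns a copy; agrees with :func:`compute_all` row by row.
    """
    required = ("fpg", "g30", "g120", "fcp", "cp30", "cp120")
    absent = [c for c in required if c not in df.columns]
    if absent:
        raise KeyError(f"cohort table lacks OGTT columns: {absent}")
    out = df.copy()
    fpg = out["fpg"].astype(float)
    g30 = out["g30"].astype(float)
    g120 = out["g120"].astype(float)
    fcp = out["fcp"].astype(float) * 1.0
    cp30 = out["cp30"].astype(float)
    cp120 = out["cp120"].astype(float)

    out["delta_c30"] = cp30 - fcp
    out["delta_c120"] = cp120 - fcp
    dg30 = g30 - fpg
    dg120 = g120 - fpg
    with np.errstate(divide="ignore", invalid="ignore"):
        out["ii30"] = np.where(dg30 == 0, np.nan, (cp30 - fcp) / dg30)
        out["ii120"] = np.where(dg120 == 0, np.nan, (cp120 - fcp) / dg120)
        out["homa_beta_cp"] = np.where(
            fpg == HOMA_BETA_GLUCOSE_OFFSET,
            np.nan,
            0.27 * fcp * unit_factor / (fpg - HOMA_BETA_GLUCOSE_OFFSET),
        )
    out["homa_ir_cp"] = HOMA_IR_FLOOR + fcp * unit_factor * fpg / HOMA_IR_SCALE
    out["cpeptide_auc"] = 0.25 * fcp + 4.0 * cp30 + 3.0 * cp120
    return out
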