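"""Statistical layer: group comparisons, univariate screen, logistic
regression, ROC / Youden analysis, and paired AUC comparison.

Conventions
-----------
* ROC positivity: a subject is called positive when score > threshold
  (mirroring the <=cutoff / >cutoff grouping used in the clinical tables);
  for systems where a *lower* score predicts the event, a direction flag
  inverts the scores before the curve is built.
* The AUC is the trapezoidal area over the operating points, which equals
  the tie-corrected Mann–Whitney concordance (ties count 1/2).
* The Youden-optimal cutoff maximizes J = sensitivity + specificity − 1,
  breaking ties toward the lowest threshold.
* Paired AUCs are compared with DeLong's test (a permutation fallback is
  available); both are labelled in the output.

Standard tests (chi-square, t, Pearson) delegate to scipy; logistic
maximum likelihood delegates to statsmodels (Newton/IRLS) behind
:func:`logistic_fit`, with separation detected and reported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

__all__ = [
    "ContingencyTable2x2",
    "RocCurve",
    "OptimalCutoff",
    "LogisticFit",
    "AucComparison",
    "SeparationError",
    "EmptyGroupError",
    "DegenerateMarginError",
    "ZeroVarianceError",
    "remission_rate",
    "chi_square",
    "two_sample_t",
    "pearson_r",
    "univariate_screen",
    "logistic_fit",
    "roc_curve",
    "youden_j",
    "optimal_cutoff",
    "auc_compare",
]


class EmptyGroupError(ValueError):
    """A rate was requested for a group with no members."""


class DegenerateMarginError(ValueError):
    """A contingency-table margin is zero; expected counts undefined."""


class ZeroVarianceError(ValueError):
    """A correlation was requested for a constant sample."""


class SeparationError(RuntimeError):
    """The logistic likelihood is unbounded (perfect/quasi separation)."""


class OneClassError(ValueError):
    """ROC analysis needs both outcome classes present."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = exposure groups, columns = (event, non-event)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for n in (self.a, self.b, self.c, self.d):
            if n < 0 or n != int(n):
                raise ValueError("counts must be nonnegative integers")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table is empty")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    @property
    def odds_ratio(self) -> float:
        if self.b * self.c == 0:
            return math.inf if self.a * self.d > 0 else math.nan
        return (self.a * self.d) / (self.b * self.c)


def remission_rate(table: ContingencyTable2x2, group: int = 0) -> float:
    """Percentage of events in one exposure row: 100 × events / row total."""
    if group == 0:
        ev, tot = table.a, table.a + table.b
    elif group == 1:
        ev, tot = table.c, table.c + table.d
    else:
        raise ValueError("group must be 0 or 1")
    if tot == 0:
        raise EmptyGroupError(f"group {group} has no members")
    return 100.0 * ev / tot


def chi_square(
    table: np.ndarray | ContingencyTable2x2 | Sequence[Sequence[int]],
    correction: bool = False,
) -> tuple[float, float, int]:
    """Pearson chi-square test of independence on an r×c table.

    Returns (statistic, p-value, degrees of freedom). Continuity
    correction is off by default.
    """
    if isinstance(table, ContingencyTable2x2):
        table = table.as_array()
    arr = np.asarray(table, dtype=float)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DegenerateMarginError("a row or column margin is zero")
    stat, p, dof, _ = scipy.stats.chi2_contingency(arr, correction=correction)
    return float(stat), float(p), int(dof)


def two_sample_t(
    x: Sequence[float], y: Sequence[float], equal_var: bool = False
) -> tuple[float, float]:
    """Two-sided two-sample t-test of mean difference (Welch by default)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    if np.var(x) == 0 and np.var(y) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        # degenerate-variance path: means differ with zero spread
        return math.copysign(math.inf, x.mean() - y.mean()), 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = scipy.stats.ttest_ind(x, y, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("paired samples with n >= 3 required")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ZeroVarianceError("a sample is constant; correlation undefined")
    res = scipy.stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------------------------
# univariate screen


def univariate_screen(
    df: pd.DataFrame,
    outcome: str,
    predictors: Mapping[str, Mapping],
    alpha: float = 0.05,
    correction: bool = False,
) -> pd.DataFrame:
    """Per-predictor contingency tests of a binary outcome.

    ``predictors`` maps a display name to a spec dict:

    * ``{"column": c, "kind": "binary"}`` — column already two-level,
    * ``{"column": c, "kind": "categorical"}`` — use the column's levels,
    * ``{"column": c, "kind": "cut", "edges": [...], "labels": [...],
      "right": False}`` — explicit numeric bins,
    * ``{"column": c, "kind": "median"}`` — dichotomize at the cohort
      median (computed after listwise exclusion on that column), levels
      ``<=median`` and ``>median``.

    Rows of the result: one per predictor level with counts and event
    rates, plus the predictor-level chi-square p-value and a flag for
    p < alpha. Predictors with fewer than two populated levels are
    excluded with a reason.
    """
    out_rows = []
    y_all = df[outcome]
    for name, spec in predictors.items():
        col = spec["column"]
        kind = spec.get("kind", "binary")
        sub = df[[col, outcome]].dropna()
        if sub.empty:
            out_rows.append(
                {"predictor": name, "excluded_reason": "no complete cases"}
            )
            continue
        x = sub[col]
        y = sub[outcome].astype(bool)
        if kind == "median":
            med = float(x.median())
            levels = pd.Series(
                np.where(x <= med, f"<={med:g}", f">{med:g}"), index=x.index
            )
            order = [f"<={med:g}", f">{med:g}"]
        elif kind == "cut":
            levels = pd.cut(
                x,
                bins=spec["edges"],
                labels=spec["labels"],
                right=spec.get("right", False),
                include_lowest=True,
            ).astype(object)
            order = list(spec["labels"])
        elif kind in ("binary", "categorical"):
            levels = x.astype(str)
            order = sorted(levels.unique(), key=str)
            if "order" in spec:
                order = [l for l in spec["order"] if l in set(levels)]
        else:
            raise ValueError(f"unknown predictor kind {kind!r}")
        tab = (
            pd.DataFrame({"level": levels, "y": y})
            .groupby("level", observed=True)["y"]
            .agg(n_remission="sum", n_total="count")
        )
        tab = tab.reindex([l for l in order if l in tab.index]).dropna()
        tab = tab[tab["n_total"] > 0]
        if len(tab) < 2:
            out_rows.append(
                {"predictor": name, "excluded_reason": "fewer than two levels"}
            )
            continue
        counts = np.column_stack(
            [tab["n_remission"], tab["n_total"] - tab["n_remission"]]
        )
        try:
            stat, p, dof = chi_square(counts, correction=correction)
        except DegenerateMarginError:
            out_rows.append(
                {"predictor": name, "excluded_reason": "degenerate margin"}
            )
            continue
        for level, r in tab.iterrows():
            out_rows.append(
                {
                    "predictor": name,
                    "level": level,
                    "n_remission": int(r["n_remission"]),
                    "n_total": int(r["n_total"]),
                    "remission_rate_pct": round(
                        100.0 * r["n_remission"] / r["n_total"], 2
                    ),
                    "chi2": stat,
                    "df": dof,
                    "p_value": p,
                    "flagged": bool(p < alpha),
                    "n_excluded": int(len(y_all) - len(sub)),
                }
            )
    return pd.DataFrame(out_rows)


# --------------------------------------------------------------------------
# logistic regression


@dataclass(frozen=True)
class LogisticFit:
    """Binary-logistic ML fit: per-predictor coefficients (log-odds),
    odds ratios with Wald CIs, p-values, and convergence metadata."""

    table: pd.DataFrame  # index: term; coef, se, odds_ratio, ci_low, ci_high, p_value
    converged: bool
    n_iter: int
    llf: float
    n_obs: int

    def coef(self, term: str) -> float:
        return float(self.table.loc[term, "coef"])

    def odds_ratio(self, term: str) -> float:
        return float(self.table.loc[term, "odds_ratio"])


def logistic_fit(
    X: pd.DataFrame,
    y: Sequence[int],
    *,
    maxiter: int = 25,
    tol: float = 1e-8,
    alpha: float = 0.05,
) -> LogisticFit:
    """Maximum-likelihood binary logistic regression (Newton/IRLS).

    ``X`` holds numeric predictor columns (indicators already encoded
    against their reference levels); an intercept is added internally.
    Raises :class:`SeparationError` when the likelihood is unbounded —
    no estimates are reported in that case.
    """
    X = pd.DataFrame(X).astype(float)
    y = np.asarray(y, dtype=float)
    if len(X) != len(y):
        raise ValueError("X and y lengths differ")
    if len(X) <= X.shape[1] + 1:
        raise ValueError("need more observations than parameters")
    design = sm.add_constant(X, has_constant="add")
    model = sm.Logit(y, design)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = model.fit(method="newton", maxiter=maxiter, tol=tol, disp=False)
    except (PerfectSeparationError, PerfectSeparationWarning) as e:
        raise SeparationError(str(e)) from e
    except np.linalg.LinAlgError as e:
        raise SeparationError(f"singular information matrix: {e}") from e
    if np.any(np.abs(res.params.to_numpy()) > 20):
        raise SeparationError(
            "coefficient magnitude > 20 on the log-odds scale; "
            "quasi-separation suspected"
        )
    ci = res.conf_int(alpha=alpha)
    table = pd.DataFrame(
        {
            "coef": res.params,
            "se": res.bse,
            "odds_ratio": np.exp(res.params),
            "ci_low": np.exp(ci[0]),
            "ci_high": np.exp(ci[1]),
            "p_value": res.pvalues,
        }
    )
    return LogisticFit(
        table=table,
        converged=bool(res.mle_retvals.get("converged", False)),
        n_iter=int(res.mle_retvals.get("iterations", -1)),
        llf=float(res.llf),
        n_obs=int(res.nobs),
    )


# --------------------------------------------------------------------------
# ROC / Youden


@dataclass(frozen=True)
class RocCurve:
    """Operating points over all distinct thresholds, plus the AUC.

    With ``direction='higher'`` a subject is positive when
    score > threshold; with ``'lower'`` when score < threshold. The
    leading sentinel threshold (−inf resp. +inf) classifies everyone
    positive.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    direction: str = "higher"

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("auc must lie in [0, 1]")


def roc_curve(
    scores: Sequence[float], labels: Sequence[bool], direction: str = "higher"
) -> RocCurve:
    """ROC curve with the positive-if-score-beyond-threshold convention.

    The AUC is the trapezoidal area, equal to the Mann–Whitney
    concordance with ties counting one half.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels lengths differ")
    if np.isnan(s).any():
        raise ValueError("scores contain NaN")
    if direction not in ("higher", "lower"):
        raise ValueError("direction must be 'higher' or 'lower'")
    if y.all() or not y.any():
        raise OneClassError("both outcome classes must be present")
    work = -s if direction == "lower" else s

    pos = np.sort(work[y])
    neg = np.sort(work[~y])
    uniq = np.unique(work)
    thresholds = np.concatenate(([-np.inf], uniq))
    # positives are scores strictly greater than the threshold
    sens = 1.0 - np.searchsorted(pos, thresholds, side="right") / len(pos)
    spec = np.searchsorted(neg, thresholds, side="right") / len(neg)
    fpr = 1.0 - spec
    # thresholds ascend, so (fpr, sens) runs from (1,1) down to (0,0)
    auc = float(abs(np.trapezoid(sens, fpr)))
    if direction == "lower":
        thresholds = -thresholds
    return RocCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        direction=direction,
    )


def youden_j(sensitivity: float, specificity: float) -> float:
    """Youden's J = sensitivity + specificity − 1."""
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    return sensitivity + specificity - 1.0


@dataclass(frozen=True)
class OptimalCutoff:
    threshold: float
    sensitivity: float
    specificity: float
    j: float


def optimal_cutoff(curve: RocCurve) -> OptimalCutoff:
    """Threshold maximizing Youden's J; ties break to the lowest threshold."""
    if len(curve.thresholds) == 0:
        raise ValueError("empty curve")
    j = curve.sensitivity + curve.specificity - 1.0
    best_j = j.max()
    # J values equal up to rounding are ties (sens/spec are count ratios)
    candidates = np.flatnonzero(j >= best_j - 1e-12)
    idx = candidates[np.argmin(curve.thresholds[candidates])]
    return OptimalCutoff(
        threshold=float(curve.thresholds[idx]),
        sensitivity=float(curve.sensitivity[idx]),
        specificity=float(curve.specificity[idx]),
        j=float(j[idx]),
    )


# --------------------------------------------------------------------------
# paired AUC comparison (DeLong)


def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    t = np.zeros(n)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        t[i:j] = 0.5 * (i + j - 1) + 1  # average 1-based rank of the tie block
        i = j
    out = np.empty(n)
    out[order] = t
    return out


@dataclass(frozen=True)
class AucComparison:
    auc_a: float
    auc_b: float
    difference: float
    variance: float
    p_value: float
    method: str


def _delong_components(scores: np.ndarray, y: np.ndarray):
    pos, neg = scores[y], scores[~y]
    m, n = len(pos), len(neg)
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n  # structural components over positives
    v10 = 1.0 - (tz[m:] - ty) / m  # over negatives
    return auc, v01, v10


def auc_compare(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[bool],
    method: str = "delong",
    n_perm: int = 2000,
    rng: np.random.Generator | None = None,
) -> AucComparison:
    """Compare two correlated AUCs measured on the same subjects.

    ``method='delong'`` uses DeLong's paired normal test on the structural
    components; ``method='permutation'`` swaps the two scores within
    subjects at random. Both score vectors must be oriented so that a
    higher score predicts a positive label.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if not (a.shape == b.shape == y.shape):
        raise ValueError("scores_a, scores_b and labels must be paired")
    if not y.any() or y.all():
        raise OneClassError("both outcome classes must be present")

    auc_a, v01_a, v10_a = _delong_components(a, y)
    auc_b, v01_b, v10_b = _delong_components(b, y)
    diff = auc_a - auc_b

    if method == "delong":
        m, n = len(v01_a), len(v10_a)
        s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
        s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
        cov = s01 / m + s10 / n
        var = float(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
        if var <= 1e-15:
            p = 1.0 if diff == 0 else 0.0
        else:
            z = diff / math.sqrt(var)
            p = 2.0 * scipy.stats.norm.sf(abs(z))
        return AucComparison(auc_a, auc_b, diff, var, float(p), "delong")
    if method == "permutation":
        rng = rng or np.random.default_rng()
        count = 0
        for _ in range(n_perm):
            swap = rng.random(len(y)) < 0.5
            pa = np.where(swap, b, a)
            pb = np.where(swap, a, b)
            d = _delong_components(pa, y)[0] - _delong_components(pb, y)[0]
            if abs(d) >= abs(diff) - 1e-12:
                count += 1
        p = (count + 1) / (n_perm + 1)
        return AucComparison(auc_a, auc_b, diff, math.nan, float(p), "permutation")
    raise ValueError("method must be 'delong' or 'permutation'")
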