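"""End-to-end analysis pipeline: cohort I/O, table assembly, and the
report bundle (univariate screen, logistic models, ROC/Youden summary,
score-band remission rates, paired AUC comparison).

Cohort interchange format: comma-separated UTF-8 CSV with a header row,
"." decimal, empty cell = missing. Every written artifact carries a
provenance comment line (package version, seed, config hash); CSVs are
read back with ``comment='#'``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__, islet, outcomes, scores, stats
from .cohort import CohortTables, SyntheticCohortParams, generate_cohort

__all__ = [
    "PipelineConfig",
    "SchemaError",
    "ValidationReport",
    "read_cohort",
    "write_cohort",
    "run_analysis",
    "write_report",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

BASELINE_COLUMNS: Mapping[str, bool] = {
    # column -> numeric?
    "patient_id": False,
    "age": True,
    "sex": False,
    "bmi": True,
    "duration": True,
    "hba1c": True,
    "n_diabetes_medications": True,
    "insulin_use": False,
    "other_antidiabetic_drug_use": False,
}
OGTT_COLUMNS = {
    "patient_id": False,
    "fpg": True,
    "g30": True,
    "g120": True,
    "fcp": True,
    "cp30": True,
    "cp120": True,
}
FOLLOWUP_COLUMNS = {
    "patient_id": False,
    "t_years": True,
    "hba1c": True,
    "fpg": True,
    "on_meds": False,
}

CPAUC_CUTOFF = scores.ACF_CPAUC_CUTOFF


class SchemaError(ValueError):
    """An input table is missing required columns."""


def _json_scalar(o):
    if hasattr(o, "item"):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


@dataclass
class ValidationReport:
    """Row-level validation outcome per table."""

    n_rows: dict[str, int] = field(default_factory=dict)
    quarantined: dict[str, list[dict]] = field(default_factory=dict)

    def add(self, table: str, n: int, bad: list[dict]) -> None:
        self.n_rows[table] = n
        self.quarantined[table] = bad


@dataclass
class PipelineConfig:
    """Everything a run needs; representable as YAML.

    Either ``input_dir`` (a directory of baseline/ogtt/followup CSVs) or
    simulation parameters are used as the cohort source.
    """

    outdir: str = "results"
    seed: int | None = None
    input_dir: str | None = None
    n: int = 87
    unit_factor: float = 1.0
    score_config_path: str | None = None
    allow_single_visit: bool = True
    chi2_correction: bool = False
    make_plots: bool = False
    auc_comparison_method: str = "delong"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        # outdir does not influence any computed number
        payload = {
            k: v for k, v in dataclasses.asdict(self).items() if k != "outdir"
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


# --------------------------------------------------------------------------
# I/O


def _provenance_line(cfg: PipelineConfig | None, seed: int | None) -> str:
    meta = {"package": f"t2drem {__version__}", "seed": seed}
    if cfg is not None:
        meta["config_sha256"] = cfg.digest()
    return "# provenance: " + json.dumps(meta, sort_keys=True)


def _write_csv(df: pd.DataFrame, path: Path, header_line: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(header_line + "\n")
        df.to_csv(fh, index=False)


def _validate_table(
    df: pd.DataFrame, spec: Mapping[str, bool], name: str
) -> tuple[pd.DataFrame, list[dict]]:
    missing_cols = [c for c in spec if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"{name}: missing columns {missing_cols}")
    df = df.copy()
    bad_rows: list[dict] = []
    bad_mask = pd.Series(False, index=df.index)
    for col, numeric in spec.items():
        if not numeric:
            continue
        raw = df[col]
        coerced = pd.to_numeric(raw, errors="coerce")
        # a value present in the file but not parseable quarantines the row
        invalid = coerced.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        for i in df.index[invalid]:
            bad_rows.append(
                {"table": name, "row": int(i), "column": col, "value": raw[i]}
            )
        bad_mask |= invalid
        df[col] = coerced
    if bad_mask.all() and len(df):
        raise SchemaError(f"{name}: every row failed validation")
    if bad_mask.any():
        logger.warning("%s: quarantined %d rows", name, int(bad_mask.sum()))
    return df[~bad_mask].reset_index(drop=True), bad_rows


def _read_bool(series: pd.Series) -> pd.Series:
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "yes": True, "no": False,
    }
    return series.map(
        lambda v: mapping.get(str(v).strip().lower(), pd.NA)
        if not pd.isna(v)
        else pd.NA
    )


def read_cohort(path: str | Path) -> tuple[CohortTables, ValidationReport]:
    """Load and validate baseline/ogtt/followup CSVs from a directory.

    Schema violations raise :class:`SchemaError`; rows with unparseable
    numeric values are quarantined (collected in the report) rather than
    fatal, unless every row fails.
    """
    path = Path(path)
    report = ValidationReport()
    tables = {}
    for name, spec in (
        ("baseline", BASELINE_COLUMNS),
        ("ogtt", OGTT_COLUMNS),
        ("followup", FOLLOWUP_COLUMNS),
    ):
        f = path / f"{name}.csv"
        if not f.exists():
            raise FileNotFoundError(f)
        df = pd.read_csv(f, comment="#")
        df, bad = _validate_table(df, spec, name)
        report.add(name, len(df), bad)
        tables[name] = df
    for col in ("insulin_use", "other_antidiabetic_drug_use"):
        tables["baseline"][col] = _read_bool(tables["baseline"][col])
    tables["followup"]["on_meds"] = _read_bool(tables["followup"]["on_meds"])
    truth_file = path / "truth.csv"
    truth = (
        pd.read_csv(truth_file, comment="#")
        if truth_file.exists()
        else pd.DataFrame(
            columns=["patient_id", "short_term_status", "long_term_status"]
        )
    )
    return (
        CohortTables(tables["baseline"], tables["ogtt"], tables["followup"], truth),
        report,
    )


def write_cohort(
    cohort: CohortTables,
    path: str | Path,
    cfg: PipelineConfig | None = None,
    seed: int | None = None,
) -> None:
    """Write the cohort tables as CSVs with a provenance header."""
    path = Path(path)
    line = _provenance_line(cfg, seed)
    for name in ("baseline", "ogtt", "followup", "truth"):
        _write_csv(getattr(cohort, name), path / f"{name}.csv", line)


# --------------------------------------------------------------------------
# analysis assembly


def _assemble(cohort: CohortTables, cfg: PipelineConfig) -> pd.DataFrame:
    """One row per patient: baseline + OGTT + derived indexes + outcomes."""
    ogtt = islet.add_indices(cohort.ogtt, unit_factor=cfg.unit_factor)
    labels = outcomes.classify_cohort(
        cohort.followup, allow_single_visit=cfg.allow_single_visit
    )
    df = cohort.baseline.merge(ogtt, on="patient_id", how="left").merge(
        labels, on="patient_id", how="left"
    )
    for col in ("short_term_status", "long_term_status"):
        df[col] = df[col].fillna(outcomes.Status.UNEVALUABLE.value)
    return df


def _outcome_indicator(df: pd.DataFrame, window: str) -> pd.Series:
    """Remission=1 vs non-remission/recurrence=0; unevaluable -> NaN."""
    col = f"{window}_term_status"
    return df[col].map(
        {
            outcomes.Status.REMISSION.value: 1.0,
            outcomes.Status.NON_REMISSION.value: 0.0,
            outcomes.Status.RECURRENCE.value: 0.0,
            outcomes.Status.UNEVALUABLE.value: np.nan,
        }
    )


def _univariate_predictors() -> dict[str, dict]:
    return {
        "age": {"column": "age", "kind": "cut", "edges": [-np.inf, 40, np.inf],
                "labels": ["<40", ">=40"]},
        "gender": {"column": "sex", "kind": "binary"},
        "duration": {"column": "duration", "kind": "cut",
                     "edges": [-np.inf, 5, np.inf], "labels": ["<=5", ">5"],
                     "right": True},
        "bmi": {"column": "bmi", "kind": "cut",
                "edges": [-np.inf, 27.5, 32.5, np.inf],
                "labels": ["<27.5", "27.5-32.5", ">=32.5"]},
        "tg": {"column": "tg", "kind": "cut", "edges": [-np.inf, 1.7, np.inf],
               "labels": ["<1.7", ">=1.7"]},
        "chol": {"column": "chol", "kind": "cut",
                 "edges": [-np.inf, 4.14, np.inf], "labels": ["<4.14", ">=4.14"]},
        "hdl": {"column": "hdl", "kind": "cut", "edges": [-np.inf, 1.29, np.inf],
                "labels": ["<=1.29", ">1.29"], "right": True},
        "ldl": {"column": "ldl", "kind": "cut", "edges": [-np.inf, 2.59, np.inf],
                "labels": ["<2.59", ">=2.59"]},
        "fpg": {"column": "fpg", "kind": "cut", "edges": [-np.inf, 7.0, np.inf],
                "labels": ["<7.0", ">=7.0"]},
        "hba1c": {"column": "hba1c", "kind": "cut",
                  "edges": [-np.inf, 6.5, 9.0, np.inf],
                  "labels": ["<6.5", "6.5-9", ">=9"]},
        "insulin_use": {"column": "insulin_use", "kind": "binary"},
        # islet-function indexes are dichotomized at the cohort median
        "fcp": {"column": "fcp", "kind": "median"},
        "delta_c30": {"column": "delta_c30", "kind": "median"},
        "delta_c120": {"column": "delta_c120", "kind": "median"},
        "ii30": {"column": "ii30", "kind": "median"},
        "ii120": {"column": "ii120", "kind": "median"},
        "homa_beta_cp": {"column": "homa_beta_cp", "kind": "median"},
        "homa_ir_cp": {"column": "homa_ir_cp", "kind": "median"},
        "cpeptide_auc": {"column": "cpeptide_auc", "kind": "median"},
    }


def _logistic_table(
    df: pd.DataFrame, window: str
) -> tuple[pd.DataFrame, str | None]:
    """Multivariable model with the covariate sets of the published layout."""
    y = _outcome_indicator(df, window)
    if window == "short":
        X = pd.DataFrame(
            {
                "cpauc_gt_30.93": (df["cpeptide_auc"] > CPAUC_CUTOFF).astype(float),
                "age_lt_40": (df["age"] < 40).astype(float),
                "bmi_27.5_32.5": df["bmi"].between(27.5, 32.5, inclusive="left")
                .astype(float),
                "bmi_ge_32.5": (df["bmi"] >= 32.5).astype(float),
                "duration_gt_5": (df["duration"] > 5).astype(float),
                "fpg_ge_7.0": (df["fpg"] >= 7.0).astype(float),
            },
            index=df.index,
        )
    else:
        X = pd.DataFrame(
            {
                "cpauc_gt_30.93": (df["cpeptide_auc"] > CPAUC_CUTOFF).astype(float),
                "fpg_lt_7.0": (df["fpg"] < 7.0).astype(float),
                "male": (df["sex"] == "male").astype(float),
                "hba1c_6.5_9": df["hba1c"].between(6.5, 9.0, inclusive="left")
                .astype(float),
                "hba1c_ge_9": (df["hba1c"] >= 9.0).astype(float),
                "bmi_27.5_32.5": df["bmi"].between(27.5, 32.5, inclusive="left")
                .astype(float),
                "bmi_ge_32.5": (df["bmi"] >= 32.5).astype(float),
            },
            index=df.index,
        )
    keep = y.notna() & df["cpeptide_auc"].notna()
    if keep.sum() < X.shape[1] + 2 or y[keep].nunique() < 2:
        return pd.DataFrame(), "insufficient evaluable patients"
    try:
        fit = stats.logistic_fit(X[keep], y[keep].astype(int))
    except stats.SeparationError as e:
        return pd.DataFrame(), f"separation: {e}"
    tab = fit.table.drop(index="const").reset_index(names="term")
    tab.insert(0, "window", window)
    return tab, None


def _score_direction(system: str) -> str:
    # lower DiaRem / IMS predicts remission
    return "lower" if system in ("DiaRem", "IMS") else "higher"


def run_analysis(cohort: CohortTables, cfg: PipelineConfig) -> dict[str, Any]:
    """Produce the full report bundle on an in-memory cohort.

    Returns a dict of DataFrames (univariate, logistic, roc_summary,
    score_bands, auc_comparison, outcomes, scores) plus a JSON-ready
    ``summary`` dict. Internal consistency of the band table against
    :func:`t2drem.stats.remission_rate` is asserted on every run.
    """
    df = _assemble(cohort, cfg)
    score_cfg = (
        scores.load_score_config(cfg.score_config_path)
        if cfg.score_config_path
        else None
    )
    score_table = scores.score_cohort(
        df, systems=scores.SYSTEMS, config=score_cfg
    )

    exclusions = {
        "missing_cpeptide_auc": int(df["cpeptide_auc"].isna().sum()),
        "short_unevaluable": int(
            (df["short_term_status"] == outcomes.Status.UNEVALUABLE.value).sum()
        ),
        "long_unevaluable": int(
            (df["long_term_status"] == outcomes.Status.UNEVALUABLE.value).sum()
        ),
    }

    univariate_parts, logistic_parts, roc_rows, band_rows, cmp_rows = [], [], [], [], []
    summary: dict[str, Any] = {
        "n_patients": int(len(df)),
        "exclusions": exclusions,
        "prevalence_pct": {},
        "logistic_errors": {},
    }

    preds = _univariate_predictors()
    for window in ("short", "long"):
        y = _outcome_indicator(df, window)
        sub = df[y.notna()].assign(_y=y.dropna())
        if len(sub):
            summary["prevalence_pct"][window] = round(
                100.0 * sub["_y"].mean(), 2
            )
        if sub["_y"].nunique() < 2 or len(sub) < 10:
            logger.warning("%s window: too few evaluable patients", window)
            continue
        uni = stats.univariate_screen(
            sub, "_y", preds, correction=cfg.chi2_correction
        )
        uni.insert(0, "window", window)
        univariate_parts.append(uni)

        logit_tab, err = _logistic_table(df, window)
        if err:
            summary["logistic_errors"][window] = err
        else:
            logistic_parts.append(logit_tab)

        # ROC of the C-peptide AUC index
        mask = sub["cpeptide_auc"].notna()
        curve = stats.roc_curve(
            sub.loc[mask, "cpeptide_auc"], sub.loc[mask, "_y"].astype(bool)
        )
        cut = stats.optimal_cutoff(curve)
        roc_rows.append(
            {
                "window": window,
                "marker": "cpeptide_auc",
                "optimal_cutoff": cut.threshold,
                "sensitivity_pct": round(100 * cut.sensitivity, 2),
                "specificity_pct": round(100 * cut.specificity, 2),
                "youden_j": round(cut.j, 3),
                "auc": round(curve.auc, 3),
                "n": int(mask.sum()),
            }
        )

        # score bands and AUC comparison against ACF
        merged = score_table.merge(
            sub[["patient_id", "_y"]], on="patient_id", how="inner"
        )
        for system, g in merged.groupby("system"):
            for band, gb in g.groupby("band"):
                n_rem = int(gb["_y"].sum())
                n_non = int((1 - gb["_y"]).sum())
                if n_rem + n_non == 0:
                    continue
                rate = stats.remission_rate(
                    stats.ContingencyTable2x2(n_rem, n_non, 0, 1), group=0
                )
                assert abs(rate - 100.0 * n_rem / (n_rem + n_non)) < 1e-9
                band_rows.append(
                    {
                        "window": window,
                        "system": system,
                        "band": band,
                        "n_remission": n_rem,
                        "n_non_remission": n_non,
                        "remission_rate_pct": round(rate, 2),
                    }
                )

        wide = merged.pivot_table(
            index="patient_id", columns="system", values="points"
        ).join(sub.set_index("patient_id")["_y"])
        wide = wide.dropna()
        if len(wide) >= 10 and wide["_y"].nunique() == 2:
            ylab = wide["_y"].astype(bool).to_numpy()
            oriented = {
                sys_: (
                    -wide[sys_].to_numpy()
                    if _score_direction(sys_) == "lower"
                    else wide[sys_].to_numpy()
                )
                for sys_ in scores.SYSTEMS
                if sys_ in wide
            }
            for sys_ in oriented:
                auc = stats.roc_curve(oriented[sys_], ylab).auc
                row = {
                    "window": window,
                    "system": sys_,
                    "auc": round(auc, 3),
                    "n": int(len(wide)),
                }
                if sys_ != "ACF" and "ACF" in oriented:
                    comp = stats.auc_compare(
                        oriented["ACF"],
                        oriented[sys_],
                        ylab,
                        method=cfg.auc_comparison_method,
                        rng=np.random.default_rng(cfg.seed),
                    )
                    row["auc_diff_vs_acf"] = round(comp.difference, 3)
                    row["p_vs_acf"] = comp.p_value
                    row["comparison_method"] = comp.method
                cmp_rows.append(row)

    result = {
        "patients": df,
        "scores": score_table,
        "univariate": pd.concat(univariate_parts, ignore_index=True)
        if univariate_parts
        else pd.DataFrame(),
        "logistic": pd.concat(logistic_parts, ignore_index=True)
        if logistic_parts
        else pd.DataFrame(),
        "roc_summary": pd.DataFrame(roc_rows),
        "score_bands": pd.DataFrame(band_rows),
        "auc_comparison": pd.DataFrame(cmp_rows),
        "summary": summary,
    }
    # conservation: band counts sum to the analysis set per system/window
    bands = result["score_bands"]
    for (window, system), g in bands.groupby(["window", "system"]):
        total = int(g["n_remission"].sum() + g["n_non_remission"].sum())
        summary.setdefault("band_totals", {})[f"{window}:{system}"] = total
    return result


def write_report(
    result: dict[str, Any], outdir: str | Path, cfg: PipelineConfig
) -> None:
    """Write the report bundle: CSV tables + machine-readable summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    line = _provenance_line(cfg, cfg.seed)
    for name in (
        "patients",
        "scores",
        "univariate",
        "logistic",
        "roc_summary",
        "score_bands",
        "auc_comparison",
    ):
        _write_csv(result[name], outdir / f"{name}.csv", line)
    summary = dict(result["summary"])
    summary["provenance"] = {
        "package": f"t2drem {__version__}",
        "seed": cfg.seed,
        "config_sha256": cfg.digest(),
    }
    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_scalar)
    if cfg.make_plots:
        _plot_roc(result, outdir)


def _plot_roc(result: dict[str, Any], outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = result["patients"]
    fig, axes = plt.subplots(1, 2, figsize=(10, 5))
    for ax, window in zip(axes, ("short", "long")):
        y = _outcome_indicator(df, window)
        mask = y.notna() & df["cpeptide_auc"].notna()
        if mask.sum() < 10 or y[mask].nunique() < 2:
            continue
        curve = stats.roc_curve(df.loc[mask, "cpeptide_auc"], y[mask].astype(bool))
        ax.plot(1 - curve.specificity, curve.sensitivity, drawstyle="steps-post")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.set_title(f"C-peptide AUC, {window}-term remission "
                     f"(AUC={curve.auc:.3f})")
    fig.tight_layout()
    fig.savefig(outdir / "roc_cpeptide_auc.png", dpi=120)
    plt.close(fig)


def run_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    """simulate-or-load → analyze → write; returns the result bundle."""
    if cfg.input_dir:
        cohort, report = read_cohort(cfg.input_dir)
        logger.info("loaded cohort: %s", report.n_rows)
    else:
        cohort = generate_cohort(SyntheticCohortParams(n=cfg.n, seed=cfg.seed))
        write_cohort(cohort, Path(cfg.outdir) / "cohort", cfg, cfg.seed)
    result = run_analysis(cohort, cfg)
    write_report(result, cfg.outdir, cfg)
    return result
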