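"""Readers, writers, configuration and the end-to-end pipeline.

The canonical interchange format is a flat CSV with one row per start
(identifiers, condition, block-phase metadata, every entry variable,
response times).  Supplementary-style XLSX tables are read through the
same path; a column-alias map absorbs unknown upstream headers.  Angle
columns are sanity-checked: values beyond pi in magnitude trigger a
degrees warning and an optional conversion.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .start_metrics import records_to_frame
from .stats_pipeline import (
    SCREENING_RESPONSES,
    confounder_check,
    fit_mixed_model,
    likelihood_ratio_test,
    screen_variables,
    select_candidates,
    step_down,
    validate_model,
)
from .synthetic_data import CohortConfig, generate_cohort

__all__ = [
    "REQUIRED_COLUMNS",
    "CANDIDATE_PREDICTORS",
    "PipelineConfig",
    "read_start_table",
    "write_start_table",
    "run_pipeline",
]

#: Columns a start table must provide (after aliasing).
REQUIRED_COLUMNS = (
    "swimmer_id",
    "sex",
    "condition",
    "tto15",
    "tto5",
    "com_x_entry",
    "hand_x_entry",
    "vx_entry",
    "vy_entry",
    "v_direction_entry",
    "v_magnitude_entry",
    "entry_angle_entry",
    "com_x_cross",
    "v_direction_cross",
    "entry_angle_cross",
    "direction_difference_cross",
)

#: The candidate predictor set screened against the three responses.
CANDIDATE_PREDICTORS = (
    "com_x_entry",
    "hand_x_entry",
    "vx_entry",
    "vy_entry",
    "v_direction_entry",
    "v_magnitude_entry",
    "entry_angle_entry",
    "com_x_cross",
    "v_direction_cross",
    "entry_angle_cross",
    "direction_difference_cross",
)

_ANGLE_COLUMNS = (
    "v_direction_entry",
    "entry_angle_entry",
    "v_direction_cross",
    "entry_angle_cross",
    "direction_difference_cross",
    "take_off_angle",
)


@dataclass
class PipelineConfig:
    """Thresholds and paths for the end-to-end analysis."""

    input_path: str | None = None
    out_dir: str = "entrystate_out"
    alias_map: dict = field(default_factory=dict)
    seed: int = 0
    p_max: float = 0.3
    r_max: float = 0.75
    alpha: float = 0.05
    confounder_threshold: float = 0.10
    selection_strategy: str = "mean_r2"
    convert_degrees: bool = False
    cohort: dict = field(default_factory=dict)

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return PipelineConfig(**data)


def read_start_table(
    path: str | Path,
    alias_map: dict | None = None,
    convert_degrees: bool = False,
) -> pd.DataFrame:
    """Read a per-start table (CSV or XLSX) into the analysis frame.

    ``alias_map`` maps source column headers to canonical names; unknown
    columns are kept as passthrough.  Missing required columns raise with
    the list of expected names.  Angle columns with values beyond pi in
    magnitude trigger a warning and, when ``convert_degrees`` is set, are
    converted from degrees to radians.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    if alias_map:
        df = df.rename(columns=dict(alias_map))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"start table lacks required columns {missing}; "
            f"declare aliases for them (expected any of {list(REQUIRED_COLUMNS)})"
        )
    for col in _ANGLE_COLUMNS:
        if col in df.columns and np.nanmax(np.abs(df[col].to_numpy(float))) > np.pi:
            warnings.warn(
                f"column {col!r} has values beyond pi; it looks like degrees"
            )
            if convert_degrees:
                df[col] = np.deg2rad(df[col])
    if "zscore15m" not in df.columns:
        df["zscore15m"] = df.groupby("swimmer_id")["tto15"].transform(
            lambda s: (s - s.mean()) / s.std(ddof=1)
        )
    if "outcome5m" not in df.columns and {"t_hip_45", "t_hip_55"} <= set(df.columns):
        df["hip_velocity_5m"] = 1.0 / (df["t_hip_55"] - df["t_hip_45"])
        df["outcome5m"] = df["hip_velocity_5m"] / df["tto5"]
    return df


def write_start_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write the analysis frame as CSV with stable float formatting."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.12g")


def _model_summary_frame(fit):
    return pd.DataFrame(
        {"coefficient": fit.params, "se": fit.bse, "p": fit.pvalues}
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Generate-or-read, screen, select, fit, validate; write the bundle.

    Returns a dict with the analysis frame, screening result, final fits
    and validation reports for both responses (TTO15 and TTO5).  All
    intermediate tables are written under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.input_path:
        df = read_start_table(
            config.input_path, config.alias_map, config.convert_degrees
        )
        truth = None
    else:
        cohort = generate_cohort(
            CohortConfig(**{"seed": config.seed, **config.cohort})
        )
        df = records_to_frame(cohort.records)
        truth = cohort.truth
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
    write_start_table(df, out / "starts.csv")

    if "sex_code" not in df.columns:
        df["sex_code"] = pd.factorize(df["sex"])[0].astype(float)

    screening = screen_variables(df, list(CANDIDATE_PREDICTORS))
    screening.r2.to_csv(out / "screening_r2.csv", float_format="%.12g")
    screening.p.to_csv(out / "screening_p.csv", float_format="%.12g")
    screening.correlations.to_csv(out / "predictor_correlations.csv",
                                  float_format="%.12g")
    selected = select_candidates(
        screening, config.p_max, config.r_max, config.selection_strategy
    )

    results = {"frame": df, "screening": screening, "selected": selected,
               "truth": truth, "models": {}}
    report_lines = [
        "entry-state analysis report",
        f"starts: {len(df)}  swimmers: {df['swimmer_id'].nunique()}",
        f"screening thresholds: p_max={config.p_max} r_max={config.r_max}",
        f"selected candidates: {', '.join(selected)}",
        "",
    ]
    for response in ("tto15", "tto5"):
        full = fit_mixed_model(df, selected, response)
        final, trace = step_down(df, list(selected), response, alpha=config.alpha)
        retained, aug, rel = confounder_check(
            df, final, covariate="sex_code", threshold=config.confounder_threshold
        )
        report_fit = aug if retained else final
        validation = validate_model(
            report_fit, df, full_fit=None if retained else full
        )
        if retained:
            # full vs pre-augmentation final (the augmented model is not
            # nested in the screened full model)
            validation.lr_full_vs_final = likelihood_ratio_test(final, full)
        _model_summary_frame(report_fit).to_csv(
            out / f"model_{response}.csv", float_format="%.12g"
        )
        validation.predicted_vs_observed.to_csv(
            out / f"predicted_vs_observed_{response}.csv",
            index=False, float_format="%.12g",
        )
        results["models"][response] = {
            "full": full, "final": final, "trace": trace,
            "sex_confounder_retained": retained, "augmented": aug,
            "coefficient_changes": rel, "validation": validation,
        }
        chi2, dof, p = validation.lr_final_vs_null
        report_lines += [
            f"[{response}] final predictors: {', '.join(report_fit.predictors) or '(none)'}",
            f"[{response}] removed: " + (
                ", ".join(f"{n} (p={p_:.3f})" for n, p_ in trace) or "(none)"),
            f"[{response}] coefficients: " + ", ".join(
                f"{k}={v:.3f}" for k, v in report_fit.params.items()),
            f"[{response}] random-intercept SD={report_fit.random_intercept_sd:.3f} s, "
            f"residual SD={report_fit.residual_sd:.3f} s",
            f"[{response}] LR vs null: chi2({dof})={chi2:.1f}, p={p:.2g}",
            f"[{response}] variance explained: "
            f"{100 * validation.fraction_explained_simple:.1f}% (1 - resid var / total), "
            f"{100 * validation.conditional_r2:.1f}% (conditional R2)",
            f"[{response}] sex confounder retained: {retained}",
            "",
        ]
    (out / "report.txt").write_text("\n".join(report_lines))
    return results
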