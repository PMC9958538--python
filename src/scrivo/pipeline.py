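"""End-to-end orchestration: cohort -> features -> labels -> models -> reports.

The feature table is wide (one row per subject), with columns named
``<level>__<metric>``: completion time for every level, error counts for
the option/search games, the seven eye-tracking metrics for the selected
challenging levels, and the drawing descriptors for copying/tracing levels.
Per-grade z-scaling is applied to the eye-tracking metrics by default.
Subjects with any missing value (lost levels, empty cleaned streams) are
excluded from every predictor set.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import levels as lv
from .config import PipelineConfig
from .drawing import (
    compute_cohort_spatial_features,
    compute_drawing_features,
    compute_trace_features,
    segment_tracts,
)
from .gaze import (
    FeatureError,
    PartitionError,
    compute_gaze_features,
    filter_confidence,
    fit_and_label_panels,
    scale_by_grade,
    select_challenging_levels,
)
from .io import GazeExportDialect, read_cohort
from .model import (
    assemble_features,
    gradient_boosted_classifier,
    nested_cv_eval,
    repeated_split_eval,
    shap_explain,
)
from .report import exploratory_summary, scanpath_plot, shap_beeswarm_plot
from .scoring import NormativeTable, label_cohort
from .synthetic import CohortSpec, bvsco_frame, gen_cohort

log = logging.getLogger("scrivo")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message carries stage and context."""


def game_log_frame(records: list) -> pd.DataFrame:
    """Tidy per-subject-per-level game log."""
    rows = []
    for r in records:
        for level, entry in r.game_log.items():
            rows.append(
                {
                    "subject_id": r.subject_id,
                    "level": level,
                    "time": entry["time"],
                    "errors": entry["errors"],
                }
            )
    return pd.DataFrame(rows)


def extract_gaze_features(records: list, levels: list, min_confidence: float, seed: int) -> pd.DataFrame:
    """Eye-tracking metrics for the given levels, one wide row per subject.

    Streams are confidence-filtered first; a level whose cleaned sample
    stream is empty, or whose partition is degenerate, contributes missing
    values (the subject is later excluded, as records with missing values
    are dropped).
    """
    layouts = lv.default_layouts()
    rows = []
    for r in records:
        row: dict = {"subject_id": r.subject_id}
        for level in levels:
            stream = r.gaze.get(level)
            layout = layouts[level]
            four = layout.n_panels == 4
            metrics = ["n_gaze", "n_fix", "mean_fix_duration", "dispersion"] + (
                [
                    "frac_gaze_target",
                    "frac_gaze_correct",
                    "frac_gaze_wrong",
                    "indecision_gaze",
                    "indecision_fix",
                ]
                if four
                else []
            )
            feats = None
            if stream is not None:
                samples = filter_confidence(stream.samples, min_confidence)
                fixations = filter_confidence(stream.fixations, min_confidence)
                try:
                    partition = fit_and_label_panels(samples, layout, seed)
                    feats = compute_gaze_features(samples, fixations, partition)
                except (FeatureError, PartitionError) as exc:
                    log.warning("%s %s: level excluded (%s)", r.subject_id, level, exc)
            for m in metrics:
                v = getattr(feats, m) if feats is not None else None
                row[f"{level}__{m}"] = np.nan if v is None else v
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")


def extract_drawing_features(records: list, tract_gap_s: float) -> pd.DataFrame:
    """Drawing descriptors for all copying/tracing levels, wide per subject."""
    tidy = []
    for r in records:
        for level, pts in r.drawings.items():
            raw = pts.copy()
            if "tract_id" in raw.columns:
                # re-derive pen lifts from recorded tract boundaries, then
                # re-segment (also catching >gap pauses inside a tract)
                raw["pen_lift"] = raw["tract_id"].diff().fillna(0) != 0
            drawing = segment_tracts(raw, tract_gap_s)
            if "in_trace" in pts.columns:
                drawing["in_trace"] = pts["in_trace"].to_numpy()
            time = r.game_log.get(level, {}).get("time", np.nan)
            feats = compute_drawing_features(drawing, time)
            if "in_trace" in drawing.columns:
                feats.out_of_trace_length, feats.out_of_trace_perc = compute_trace_features(drawing)
            d = feats.to_dict()
            d.pop("distance_from_center")
            tidy.append({"subject_id": r.subject_id, "level": level, **d})
    tidy = pd.DataFrame(tidy)
    tidy, _ = compute_cohort_spatial_features(tidy)
    wide = {}
    for level, sub in tidy.groupby("level"):
        cols = [
            c
            for c in sub.columns
            if c not in ("subject_id", "level", "time")
            and sub[c].notna().any()
        ]
        block = sub.set_index("subject_id")[cols]
        block.columns = [f"{level}__{c}" for c in cols]
        wide[level] = block
    return pd.concat(wide.values(), axis=1)


def extract_feature_table(records: list, norms: NormativeTable, config: PipelineConfig):
    """Full per-subject feature table, challenge selection, and risk labels.

    Returns (features, labels_frame, challenging_levels, meta).
    """
    config.validate()
    logs = game_log_frame(records)
    gaze_logs = logs[logs["level"].isin(lv.gaze_levels())]
    challenging = select_challenging_levels(gaze_logs, config.n_challenging_levels)
    log.info("challenging levels: %s", challenging)

    # game features: time everywhere, errors where collected
    time_w = logs.pivot(index="subject_id", columns="level", values="time")
    time_w.columns = [f"{c}__time" for c in time_w.columns]
    err = logs.dropna(subset=["errors"])
    err_w = err.pivot(index="subject_id", columns="level", values="errors")
    err_w.columns = [f"{c}__errors" for c in err_w.columns]

    eye_w = extract_gaze_features(records, challenging, config.min_confidence, config.seed)
    draw_w = extract_drawing_features(records, config.tract_gap_s)

    features = pd.concat([time_w, err_w, eye_w, draw_w], axis=1).sort_index()
    features = features[sorted(features.columns)]

    meta = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "grade": [r.grade for r in records],
            "sex": [r.sex for r in records],
            "sus": [r.questionnaire.get("sus", np.nan) for r in records],
        }
    ).set_index("subject_id")

    if config.scaling_scope != "none":
        from .model import feature_family

        if config.scaling_scope == "eye":
            cols = [c for c in features.columns if feature_family(c) == "eye"]
        else:
            cols = list(features.columns)
        tmp = features.join(meta["grade"])
        tmp = scale_by_grade(tmp, "grade", cols)
        features = tmp.drop(columns="grade")

    labels = label_cohort(bvsco_frame(records), norms).set_index("subject_id")
    return features, labels, challenging, meta


def run_full_pipeline(config: PipelineConfig) -> dict:
    """simulate/read -> clean -> features -> label -> evaluate -> explain.

    Writes feature and label CSVs, a baselines table (repeated splits), a
    nested-CV table with per-set JSON reports, Shapley summaries and a run
    manifest into ``config.out_dir``; re-running with the same manifest
    reproduces the files byte for byte.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "simulate" if config.simulate else "read"
    try:
        if config.simulate:
            spec = CohortSpec.default(config.n_subjects, config.seed, config.effect_scale)
            records = gen_cohort(spec)
            norms = spec.norms
        else:
            records, norms = read_cohort(config.input_dir, GazeExportDialect(**config.dialect))

        stage = "features"
        features, labels, challenging, meta = extract_feature_table(records, norms, config)
        features.to_csv(out / "features.csv")
        labels.to_csv(out / "labels.csv")
        meta.to_csv(out / "demographics.csv")

        stage = "exploratory"
        summary_tab = meta.join(bvsco_frame(records).set_index("subject_id")[["c1", "c2", "c3"]])
        summary_tab = summary_tab.join(labels[["n_over_threshold"]])
        summary_tab["mean_level_time"] = game_log_frame(records).groupby("subject_id")["time"].mean()
        expl = exploratory_summary(summary_tab.reset_index(drop=True))
        (out / "exploratory.json").write_text(
            json.dumps(
                {
                    "sex_ttests": expl["sex_ttests"],
                    "significant_pairs": expl["significant_pairs"],
                    "constant_columns": expl["constant_columns"],
                    "sus_mean": float(summary_tab["sus"].mean()),
                    "sus_sd": float(summary_tab["sus"].std(ddof=1)),
                    "n_at_risk": int(labels["at_risk"].sum()),
                    "n_not_at_risk": int((~labels["at_risk"]).sum()),
                },
                indent=1,
                sort_keys=True,
            )
        )

        stage = "evaluate"
        y = labels["at_risk"]
        baseline_rows, nested_rows = [], []
        for set_name in config.feature_sets:
            matrix = assemble_features(features, y, set_name, challenging)
            base = repeated_split_eval(
                matrix, config.n_repeats, config.test_frac, config.seed
            ).reset_index()
            base.insert(0, "set", set_name)
            baseline_rows.append(base)
            report = nested_cv_eval(
                matrix,
                outer_k=config.outer_k,
                inner_k=config.inner_k,
                grid=config.grid,
                seed=config.seed,
                top_k=config.top_k_features,
                selection_mode=config.selection_mode,
                cohort_center_mode=config.cohort_center_mode,
            )
            (out / f"nested_{set_name}.json").write_text(report.to_json())
            nested_rows.append(report.table_row())

            stage = f"explain:{set_name}"
            est = gradient_boosted_classifier(config.seed).fit(
                matrix.X.to_numpy(float), matrix.y.to_numpy(bool)
            )
            summary, _ = shap_explain(est, matrix, top_k=min(10, matrix.X.shape[1]))
            summary.to_frame().to_csv(out / f"shap_{set_name}.csv")
            if config.make_plots:
                shap_beeswarm_plot(summary, out / f"shap_{set_name}.png")
            stage = "evaluate"

        pd.concat(baseline_rows, ignore_index=True).to_csv(out / "baselines_table.csv", index=False)
        pd.DataFrame(nested_rows).to_csv(out / "nested_cv_table.csv", index=False)

        if config.make_plots and config.simulate and challenging:
            lev = challenging[0]
            rec = records[0]
            if lev in rec.gaze:
                scanpath_plot(
                    filter_confidence(rec.gaze[lev].fixations, config.min_confidence),
                    path=out / "scanpath_example.png",
                    title=f"{rec.subject_id} {lev}",
                )

        stage = "manifest"
        import lightgbm
        import scipy
        import sklearn

        from . import __version__

        manifest = {
            "config": json.loads(json.dumps(config.__dict__, default=list)),
            "challenging_levels": challenging,
            "versions": {
                "scrivo": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "scikit-learn": sklearn.__version__,
                "scipy": scipy.__version__,
                "lightgbm": lightgbm.__version__,
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    except Exception as exc:  # annotate failures with the failing stage
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    return {
        "out_dir": str(out),
        "challenging_levels": challenging,
        "n_subjects_analyzed": int(features.dropna().shape[0]),
        "n_at_risk": int(labels["at_risk"].sum()),
    }
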