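"""Risk classification: feature-set assembly, baseline repeated splits,
nested cross-validation with a gradient-boosted classifier, and Shapley
attributions.

The five predictor sets mirror the screening study's comparison: game
performance only, eye tracking (metrics from the most challenging levels
plus those levels' time/errors), drawing, game + drawing, and everything.

Baselines (Gaussian naive Bayes, random forest, SVM, gradient-boosted
trees) are evaluated over repeated random stratified 80/20 splits; the
main model is a LightGBM classifier inside stratified 5-fold nested CV,
with a small inner 3-fold grid.  Shapley values use LightGBM's exact
tree-path-dependent algorithm.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, f1_score, precision_score, recall_score
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .scoring import ConfigurationError

FEATURE_SETS = ("game", "eye", "drawing", "game_and_drawing", "all")

GAZE_METRICS = (
    "n_gaze",
    "n_fix",
    "mean_fix_duration",
    "frac_gaze_target",
    "frac_gaze_correct",
    "frac_gaze_wrong",
    "indecision_gaze",
    "indecision_fix",
    "dispersion",
)

#: inner-loop hyperparameter grid for the boosted classifier
DEFAULT_GRID = {
    "max_depth": [3, 5],
    "n_estimators": [100, 300],
    "learning_rate": [0.05, 0.1],
}


class EvaluationError(ValueError):
    """Evaluation cannot run (single class, class too small, ...)."""


def feature_family(column: str) -> str:
    """Family tag of a feature column named ``<level>__<metric>``."""
    metric = column.split("__", 1)[1] if "__" in column else column
    if metric in ("time", "errors"):
        return "game"
    if metric in GAZE_METRICS:
        return "eye"
    return "drawing"


@dataclass
class FeatureMatrix:
    X: pd.DataFrame  # numeric, indexed by subject_id, no missing values
    y: pd.Series  # bool at_risk, same index
    families: dict  # column -> family
    set_name: str = "all"

    def __post_init__(self) -> None:
        if self.X.isna().any().any():
            raise ValueError("feature matrix must not contain missing values")


def assemble_features(
    features: pd.DataFrame,
    labels: pd.Series,
    set_name: str,
    challenging_levels: list | None = None,
) -> FeatureMatrix:
    """Build one predictor set from the full per-subject feature table.

    ``features`` is wide (one row per subject, indexed by subject_id) with
    columns ``<level>__<metric>``.  Subjects with *any* missing value in the
    full table are excluded from every set, so all sets share the same
    cohort.  The eye set contains the eye-tracking metrics of the selected
    challenging levels plus those levels' time/error columns.
    """
    if set_name not in FEATURE_SETS:
        raise ConfigurationError(f"unknown feature set {set_name!r}; choose from {FEATURE_SETS}")
    complete = features.dropna(axis=0, how="any")
    labels = labels.loc[complete.index]
    families = {c: feature_family(c) for c in complete.columns}

    drawing_levels = {c.split("__")[0] for c, f in families.items() if f == "drawing"}

    def _is_drawing_set_col(c: str) -> bool:
        # the drawing set carries the drawing descriptors plus the copying/
        # tracing completion times (the study's drawing model includes them)
        f = families[c]
        return f == "drawing" or (
            f == "game" and c.split("__")[0] in drawing_levels and c.endswith("__time")
        )

    if set_name == "game":
        cols = [c for c, f in families.items() if f == "game"]
    elif set_name == "drawing":
        cols = [c for c in families if _is_drawing_set_col(c)]
    elif set_name == "game_and_drawing":
        cols = [c for c, f in families.items() if f in ("game", "drawing")]
    elif set_name == "eye":
        if not challenging_levels:
            raise ConfigurationError("eye set needs the selected challenging levels")
        cols = [
            c
            for c, f in families.items()
            if (f == "eye" and c.split("__")[0] in challenging_levels)
            or (f == "game" and c.split("__")[0] in challenging_levels)
        ]
    else:  # all
        cols = list(complete.columns)
    if not cols:
        raise ConfigurationError(f"feature set {set_name!r} selected no columns")
    return FeatureMatrix(
        X=complete[cols],
        y=labels.astype(bool),
        families={c: families[c] for c in cols},
        set_name=set_name,
    )


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def gradient_boosted_classifier(seed: int = 0, **params) -> LGBMClassifier:
    """Gradient-boosted tree classifier for small tabular cohorts.

    Defaults are deliberately low-regularization (tiny leaves allowed) to
    behave like the aggressive boosted-tree defaults typical of this kind of
    small-sample analysis; the nested-CV grid controls capacity.
    """
    defaults = dict(
        n_estimators=200,
        learning_rate=0.1,
        num_leaves=31,
        min_child_samples=2,
        min_split_gain=0.0,
        subsample=1.0,
        colsample_bytree=1.0,
        random_state=seed,
        n_jobs=1,
        verbose=-1,
    )
    defaults.update(params)
    if "max_depth" in params and "num_leaves" not in params:
        defaults["num_leaves"] = min(31, 2 ** params["max_depth"] - 1)
    return LGBMClassifier(**defaults)


def baseline_estimators(seed: int = 0) -> dict:
    """The four baseline classifiers at default settings."""
    return {
        "gaussian_naive_bayes": GaussianNB(),
        "random_forest": RandomForestClassifier(random_state=seed, n_jobs=1),
        "svm": SVC(random_state=seed),
        "gradient_boosted_trees": gradient_boosted_classifier(seed),
    }


def _metrics(y_true, y_pred) -> dict:
    return {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "precision": float(precision_score(y_true, y_pred, zero_division=0)),
        "recall": float(recall_score(y_true, y_pred, zero_division=0)),
        "f1": float(f1_score(y_true, y_pred, zero_division=0)),
    }


def repeated_split_eval(
    matrix: FeatureMatrix,
    n_repeats: int = 6,
    test_frac: float = 0.2,
    seed: int = 0,
    algorithms: dict | None = None,
) -> pd.DataFrame:
    """Fit each baseline over repeated random stratified splits.

    Returns a frame indexed by algorithm with mean/SD train and test
    accuracy over the repeats.
    """
    y = matrix.y.to_numpy(bool)
    if len(np.unique(y)) < 2:
        raise EvaluationError("both classes must be present")
    if len(y) < 10:
        raise EvaluationError("need at least 10 subjects")
    X = matrix.X.to_numpy(float)
    algorithms = algorithms or baseline_estimators(seed)
    splitter = StratifiedShuffleSplit(n_splits=n_repeats, test_size=test_frac, random_state=seed)
    splits = list(splitter.split(X, y))
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, proto in algorithms.items():
            tr_acc, te_acc = [], []
            for tr, te in splits:
                est = clone_estimator(proto)
                est.fit(X[tr], y[tr])
                tr_acc.append(accuracy_score(y[tr], est.predict(X[tr])))
                te_acc.append(accuracy_score(y[te], est.predict(X[te])))
            rows.append(
                {
                    "algorithm": name,
                    "train_mean": float(np.mean(tr_acc)),
                    "train_sd": float(np.std(tr_acc, ddof=1)),
                    "test_mean": float(np.mean(te_acc)),
                    "test_sd": float(np.std(te_acc, ddof=1)),
                }
            )
    return pd.DataFrame(rows).set_index("algorithm")


def clone_estimator(est):
    from sklearn.base import clone

    return clone(est)


# ---------------------------------------------------------------------------
# nested cross-validation
# ---------------------------------------------------------------------------

@dataclass
class ModelReport:
    set_name: str
    folds: list  # per-fold dicts: best_params, train metrics, test metrics
    aggregate: dict  # mean/sd per metric, train and test
    selected_features: list | None
    seed: int
    config: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "set_name": self.set_name,
                "folds": self.folds,
                "aggregate": self.aggregate,
                "selected_features": self.selected_features,
                "seed": self.seed,
                "config": self.config,
            },
            indent=1,
            sort_keys=True,
        )

    def table_row(self) -> dict:
        """One Table-3-style row: mean (SD) of the four metrics, train/test."""
        row = {"set": self.set_name}
        for split in ("train", "test"):
            for m in ("accuracy", "precision", "recall", "f1"):
                row[f"{m}_{split}"] = self.aggregate[split][m]["mean"]
                row[f"{m}_{split}_sd"] = self.aggregate[split][m]["sd"]
        return row


def _grid_combos(grid: dict) -> list:
    keys = sorted(grid)
    return [dict(zip(keys, vals)) for vals in itertools.product(*(grid[k] for k in keys))]


def _inner_oof_predictions(X, y, params, inner_k, seed):
    """Out-of-fold predictions of one config over the inner folds."""
    skf = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=seed)
    pred = np.zeros_like(y, dtype=bool)
    for tr, va in skf.split(X, y):
        est = gradient_boosted_classifier(seed, **params)
        est.fit(X[tr], y[tr])
        pred[va] = est.predict(X[va]).astype(bool)
    return pred


def _recompute_fold_centers(X: pd.DataFrame, train_index: np.ndarray) -> pd.DataFrame:
    """Train-only cohort centers: recompute ``distance_from_center`` columns
    from training-fold centroid means (leak-free variant)."""
    X = X.copy()
    for col in [c for c in X.columns if c.endswith("__distance_from_center")]:
        level = col.split("__")[0]
        cxc, cyc = f"{level}__centroid_x", f"{level}__centroid_y"
        if cxc in X.columns and cyc in X.columns:
            cx = X[cxc].iloc[train_index].mean()
            cy = X[cyc].iloc[train_index].mean()
            X[col] = np.hypot(X[cxc] - cx, X[cyc] - cy)
    return X


def nested_cv_eval(
    matrix: FeatureMatrix,
    outer_k: int = 5,
    inner_k: int = 3,
    grid: dict | None = None,
    seed: int = 0,
    top_k: int | None = None,
    selection_mode: str = "per_fold",
    cohort_center_mode: str = "full",
) -> ModelReport:
    """Stratified nested cross-validation of the boosted classifier.

    Per outer fold, an inner stratified ``inner_k``-fold grid search run on
    the outer-train portion only selects the hyperparameters; "train"
    metrics are the selected configuration's inner out-of-fold metrics on
    the outer-train portion (a cross-validated estimate, so that train and
    test metrics are comparable), and test metrics come from a refit on the
    full outer-train applied to the held-out outer-test.  Outer-test data
    never touch fitting or selection.

    Optional Shapley-based feature selection keeps the ``top_k`` features
    ranked inside each outer-train fold (``selection_mode='per_fold'``) or
    once globally before the CV (``'global'``, the leaky variant).
    """
    grid = grid or DEFAULT_GRID
    y = matrix.y.to_numpy(bool)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise EvaluationError("both classes must be present")
    if counts.min() < outer_k:
        raise EvaluationError(
            f"smallest class has {counts.min()} members; needs >= outer_k={outer_k}"
        )
    if selection_mode not in ("per_fold", "global"):
        raise ConfigurationError(f"unknown selection_mode {selection_mode!r}")

    Xdf = matrix.X
    feature_names = list(Xdf.columns)
    if top_k is not None and selection_mode == "global":
        est = gradient_boosted_classifier(seed).fit(Xdf.to_numpy(float), y)
        summary, _ = shap_explain(est, matrix, top_k)
        feature_names = summary.selected
        Xdf = Xdf[feature_names]

    combos = _grid_combos(grid)
    outer = StratifiedKFold(n_splits=outer_k, shuffle=True, random_state=seed)
    folds = []
    selected_union: list = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for fold_i, (tr, te) in enumerate(outer.split(Xdf.to_numpy(float), y)):
            Xf = (
                _recompute_fold_centers(Xdf, tr)
                if cohort_center_mode == "train"
                else Xdf
            )
            cols = list(Xf.columns)
            if top_k is not None and selection_mode == "per_fold":
                est = gradient_boosted_classifier(seed).fit(
                    Xf.iloc[tr].to_numpy(float), y[tr]
                )
                fold_matrix = FeatureMatrix(
                    Xf.iloc[tr], matrix.y.iloc[tr], {c: matrix.families[c] for c in cols}
                )
                summary, _ = shap_explain(est, fold_matrix, top_k)
                cols = summary.selected
                selected_union.extend(c for c in cols if c not in selected_union)
            X = Xf[cols].to_numpy(float)

            best_params, best_acc, best_pred = None, -np.inf, None
            for params in combos:
                pred = _inner_oof_predictions(X[tr], y[tr], params, inner_k, seed + fold_i)
                acc = accuracy_score(y[tr], pred)
                if acc > best_acc:
                    best_params, best_acc, best_pred = params, acc, pred
            train_metrics = _metrics(y[tr], best_pred)
            est = gradient_boosted_classifier(seed, **best_params)
            est.fit(X[tr], y[tr])
            test_metrics = _metrics(y[te], est.predict(X[te]).astype(bool))
            folds.append(
                {
                    "fold": fold_i,
                    "best_params": best_params,
                    "n_train": int(len(tr)),
                    "n_test": int(len(te)),
                    "features": cols,
                    "train": train_metrics,
                    "test": test_metrics,
                }
            )

    aggregate = {}
    for split in ("train", "test"):
        aggregate[split] = {}
        for m in ("accuracy", "precision", "recall", "f1"):
            vals = np.array([f[split][m] for f in folds])
            aggregate[split][m] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1))}

    return ModelReport(
        set_name=matrix.set_name,
        folds=folds,
        aggregate=aggregate,
        selected_features=(
            selected_union
            if (top_k is not None and selection_mode == "per_fold")
            else (feature_names if top_k is not None else None)
        ),
        seed=seed,
        config={
            "outer_k": outer_k,
            "inner_k": inner_k,
            "grid": grid,
            "top_k": top_k,
            "selection_mode": selection_mode,
            "cohort_center_mode": cohort_center_mode,
        },
    )


# ---------------------------------------------------------------------------
# Shapley attribution
# ---------------------------------------------------------------------------

@dataclass
class ShapSummary:
    feature_names: list
    values: np.ndarray  # (n_subjects, n_features) signed Shapley values
    base_value: float  # expected raw model output
    mean_abs: pd.Series  # per-feature mean |Shapley value|, descending
    mean_signed: pd.Series
    value_direction: pd.Series  # corr(feature value, Shapley value)
    selected: list  # the top_k features

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean_abs_shap": self.mean_abs,
                "mean_signed_shap": self.mean_signed.loc[self.mean_abs.index],
                "value_direction": self.value_direction.loc[self.mean_abs.index],
                "selected": [f in self.selected for f in self.mean_abs.index],
            }
        )


def shap_explain(model, matrix: FeatureMatrix, top_k: int = 10):
    """Exact tree-path-dependent Shapley values for a fitted boosted model.

    Returns (ShapSummary, reduced FeatureMatrix restricted to the top_k
    features by mean |Shapley value|).  Per subject, the Shapley values plus
    the base value sum to the model's raw (log-odds) output.
    """
    names = list(matrix.X.columns)
    if top_k > len(names):
        warnings.warn(f"top_k={top_k} > {len(names)} features; clipping")
        top_k = len(names)
    booster = model.booster_ if hasattr(model, "booster_") else model
    contrib = booster.predict(matrix.X.to_numpy(float), pred_contrib=True)
    values, base = contrib[:, :-1], float(contrib[0, -1])
    mean_abs = pd.Series(np.abs(values).mean(axis=0), index=names).sort_values(
        ascending=False, kind="mergesort"
    )
    mean_signed = pd.Series(values.mean(axis=0), index=names)
    direction = pd.Series(
        [
            _safe_corr(matrix.X[n].to_numpy(float), values[:, i])
            for i, n in enumerate(names)
        ],
        index=names,
    )
    selected = list(mean_abs.index[:top_k])
    reduced = FeatureMatrix(
        X=matrix.X[selected],
        y=matrix.y,
        families={c: matrix.families[c] for c in selected},
        set_name=matrix.set_name,
    )
    summary = ShapSummary(
        feature_names=names,
        values=values,
        base_value=base,
        mean_abs=mean_abs,
        mean_signed=mean_signed,
        value_direction=direction,
        selected=selected,
    )
    return summary, reduced


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])
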