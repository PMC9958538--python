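"""Gaze cleaning, screen partitioning, and eye-tracking metrics.

Gaze samples and fixations are pandas DataFrames:

* gaze: columns ``t`` (s from level start), ``x``, ``y`` (normalized screen
  coordinates, origin bottom-left), ``confidence`` in [0, 1];
* fixations: ``t_start`` (s), ``duration`` (ms), ``x``, ``y``,
  ``confidence``.

For four-panel levels the screen is partitioned with a two-stage K-means
(two horizontal clusters on x, then three vertical sub-clusters of the
right one on y) and each cluster inherits the task role of its panel
position.  Seven metrics are derived per level: counts of gaze positions
and fixations, mean fixation duration, per-role gaze fractions, gaze- and
fixation-based indecision (bounces between target and options), and the
Standard Distance dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .levels import (
    PANEL_POSITIONS,
    ROLE_CORRECT,
    ROLE_TARGET,
    ROLE_WRONG,
    LayoutError,
    LevelLayout,
)

GAZE_COLUMNS = ["t", "x", "y", "confidence"]
FIXATION_COLUMNS = ["t_start", "duration", "x", "y", "confidence"]

DEFAULT_MIN_CONFIDENCE = 0.70


class PartitionError(ValueError):
    """Screen partition could not be fitted (degenerate input)."""


class FeatureError(ValueError):
    """Metrics cannot be computed (e.g. no retained samples)."""


def filter_confidence(frame: pd.DataFrame, min_conf: float = DEFAULT_MIN_CONFIDENCE) -> pd.DataFrame:
    """Keep rows with confidence >= min_conf (inclusive), order preserved."""
    if not 0.0 <= min_conf <= 1.0:
        raise ValueError(f"min_conf must be in [0, 1], got {min_conf}")
    return frame.loc[frame["confidence"] >= min_conf].reset_index(drop=True)


@dataclass
class PanelPartition:
    """Cluster model mapping screen positions to labeled panels.

    Any point is assigned to the nearest cluster center (Euclidean).
    """

    cluster_centers: np.ndarray  # (k, 2)
    position_of_cluster: dict = field(default_factory=dict)  # cluster -> panel position
    role_of_cluster: dict = field(default_factory=dict)  # cluster -> role

    def assign(self, x, y) -> np.ndarray:
        """Nearest-center cluster index for each point."""
        pts = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
        d2 = ((pts[:, None, :] - self.cluster_centers[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)

    def roles(self, x, y) -> np.ndarray:
        return np.array([self.role_of_cluster[c] for c in self.assign(x, y)])


def _kmeans_1d(values: np.ndarray, k: int, seed: int) -> np.ndarray:
    if np.unique(values).size < k:
        raise PartitionError(f"need at least {k} distinct values for k-means (k={k})")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(values.reshape(-1, 1))


def fit_and_label_panels(samples: pd.DataFrame, layout: LevelLayout, seed: int = 0) -> PanelPartition:
    """Fit the two-stage K-means screen partition and attach panel roles.

    Stage 1 splits all samples into two clusters on x; the cluster with the
    smaller mean x is the left panel.  Stage 2 splits the right cluster's
    samples into three clusters on y, ordered top to bottom by decreasing
    mean y.  Final centers are the member means of each panel.
    """
    if layout.n_panels == 1:
        if len(samples) == 0:
            raise PartitionError("no samples to partition")
        center = samples[["x", "y"]].mean().to_numpy()[None, :]
        role = layout.role_by_position.get("full", ROLE_TARGET)
        return PanelPartition(center, {0: "full"}, {0: role})

    if len(samples) < 4:
        raise PartitionError("four-panel partition needs at least 4 samples")
    x = samples["x"].to_numpy(float)
    y = samples["y"].to_numpy(float)

    lab1 = _kmeans_1d(x, 2, seed)
    mean_x = [x[lab1 == c].mean() for c in (0, 1)]
    left_c = int(np.argmin(mean_x))
    right_mask = lab1 != left_c

    lab2 = _kmeans_1d(y[right_mask], 3, seed)
    sub_mean_y = [y[right_mask][lab2 == c].mean() for c in (0, 1, 2)]
    order = np.argsort(sub_mean_y)[::-1]  # decreasing mean y: top, middle, bottom

    centers = np.empty((4, 2))
    centers[0] = [x[~right_mask].mean(), y[~right_mask].mean()]
    position_of_cluster = {0: "left"}
    for i, sub in enumerate(order):
        m = lab2 == sub
        centers[i + 1] = [x[right_mask][m].mean(), y[right_mask][m].mean()]
        position_of_cluster[i + 1] = PANEL_POSITIONS[i + 1]

    role_of_cluster = {
        c: layout.role_by_position[pos] for c, pos in position_of_cluster.items()
    }
    return PanelPartition(centers, position_of_cluster, role_of_cluster)


@dataclass
class GazeFeatureSet:
    """The per-level eye-tracking metrics."""

    n_gaze: int
    n_fix: int | None
    mean_fix_duration: float | None  # ms
    frac_gaze_target: float | None
    frac_gaze_correct: float | None
    frac_gaze_wrong: float | None
    indecision_gaze: int | None
    indecision_fix: int | None
    dispersion: float  # Standard Distance, normalized-screen units

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _count_bounces(roles: np.ndarray) -> int:
    """Transitions between consecutive events where roles differ and one
    side is the TARGET (option<->option moves are not bounces)."""
    if len(roles) < 2:
        return 0
    a, b = roles[:-1], roles[1:]
    return int(np.sum((a != b) & ((a == ROLE_TARGET) | (b == ROLE_TARGET))))


def standard_distance(x, y) -> float:
    """Standard Distance of a point pattern (population 1/n form):
    sqrt(mean((x - x_bar)^2 + (y - y_bar)^2))."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    return float(np.sqrt(np.mean((x - x.mean()) ** 2 + (y - y.mean()) ** 2)))


def compute_gaze_features(
    samples: pd.DataFrame,
    fixations: pd.DataFrame,
    partition: PanelPartition,
) -> GazeFeatureSet:
    """Compute the seven eye-tracking metrics for one level.

    Inputs are assumed confidence-filtered; the partition must have been
    fitted on these samples.  Empty samples raise (the level is excluded);
    empty fixations leave fixation-derived fields as None (missing).
    """
    if len(samples) == 0:
        raise FeatureError("no gaze samples retained for this level")
    four_panel = len(partition.cluster_centers) == 4

    roles_g = partition.roles(samples["x"], samples["y"])
    disp = standard_distance(samples["x"], samples["y"])

    if four_panel:
        n = len(roles_g)
        frac_t = float(np.mean(roles_g == ROLE_TARGET))
        frac_c = float(np.mean(roles_g == ROLE_CORRECT))
        frac_w = float(np.mean(roles_g == ROLE_WRONG))
        ind_g = _count_bounces(roles_g)
    else:
        frac_t = frac_c = frac_w = None
        ind_g = None

    if len(fixations) == 0:
        n_fix = mean_dur = ind_f = None
    else:
        fix = fixations.sort_values("t_start")
        n_fix = int(len(fix))
        mean_dur = float(fix["duration"].mean())
        if four_panel:
            ind_f = _count_bounces(partition.roles(fix["x"], fix["y"]))
        else:
            ind_f = None

    return GazeFeatureSet(
        n_gaze=int(len(samples)),
        n_fix=n_fix,
        mean_fix_duration=mean_dur,
        frac_gaze_target=frac_t,
        frac_gaze_correct=frac_c,
        frac_gaze_wrong=frac_w,
        indecision_gaze=ind_g,
        indecision_fix=ind_f,
        dispersion=disp,
    )


def scale_by_grade(
    table: pd.DataFrame,
    grade_col: str = "grade",
    columns: list | None = None,
) -> pd.DataFrame:
    """Z-score features within each grade group.

    Uses the population SD (ddof=0); groups of size one or with zero spread
    scale to 0.  Non-selected columns are returned unchanged.
    """
    if grade_col not in table.columns:
        raise ValueError(f"missing grade column {grade_col!r}")
    out = table.copy()
    if columns is None:
        columns = [
            c
            for c in table.columns
            if c != grade_col and pd.api.types.is_numeric_dtype(table[c])
        ]
    for col in columns:
        grouped = out.groupby(grade_col)[col]
        mean = grouped.transform("mean")
        sd = grouped.transform(lambda v: v.std(ddof=0))
        centered = out[col] - mean
        with np.errstate(invalid="ignore", divide="ignore"):
            z = centered / sd
        out[col] = z.where((sd > 0) & centered.notna(), 0.0).where(out[col].notna())
    return out


def select_challenging_levels(game_logs: pd.DataFrame, n_select: int = 2) -> list:
    """Rank levels by across-subject variance of completion time.

    ``game_logs`` is tidy: columns ``subject_id``, ``level``, ``time`` and
    optionally ``errors``.  Ties on time variance break on errors variance
    (descending); remaining ties keep first-appearance order.
    """
    if game_logs["subject_id"].nunique() < 2:
        raise ValueError("need at least 2 subjects to rank level difficulty")
    levels = list(dict.fromkeys(game_logs["level"]))
    rows = []
    for i, lev in enumerate(levels):
        sub = game_logs[game_logs["level"] == lev]
        tvar = float(sub["time"].var(ddof=1))
        evar = (
            float(sub["errors"].var(ddof=1))
            if "errors" in sub.columns and sub["errors"].notna().any()
            else 0.0
        )
        rows.append((lev, tvar, evar, i))
    rows.sort(key=lambda r: (-r[1], -r[2], r[3]))
    return [r[0] for r in rows[:n_select]]
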