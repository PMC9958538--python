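"""Stroke segmentation and drawing/tracing feature extraction.

A drawing is a pandas DataFrame of timestamped points with columns ``t``
(s), ``x``, ``y`` (normalized screen coordinates), ``tract_id`` (ordinal of
the pen-down segment, contiguous from 0) and, for tracing levels,
``in_trace`` (bool).

Features mirror the screening battery's drawing descriptors: tract
discontinuity (summed gap distance between consecutive tracts), the
fraction of discontinuous tract onsets, total inked length, centroid
coordinates, distance of the centroid from the cohort center, mean
dispersions from the centroid and from the starting point, and completion
time; tracing levels add out-of-trace length and point fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_TRACT_GAP_S = 0.100  # pen considered lifted after a 100 ms pause


class ContractError(ValueError):
    """Input points violate the drawing contract (e.g. missing flags)."""


def segment_tracts(
    points: pd.DataFrame,
    gap_threshold_s: float = DEFAULT_TRACT_GAP_S,
) -> pd.DataFrame:
    """Split a time-sorted point stream into pen-down tracts.

    A new tract starts at every explicit pen-lift event (boolean column
    ``pen_lift`` marking the first point after a lift, when present) and
    whenever the inter-point time gap exceeds ``gap_threshold_s``.
    Resulting ``tract_id`` values are contiguous from 0.
    """
    if len(points) == 0:
        out = points.copy()
        out["tract_id"] = pd.Series([], dtype=int)
        return out
    t = points["t"].to_numpy(float)
    if np.any(np.diff(t) < 0):
        raise ContractError("points must be time-sorted")
    breaks = np.zeros(len(points), dtype=bool)
    breaks[1:] = np.diff(t) > gap_threshold_s
    if "pen_lift" in points.columns:
        breaks |= points["pen_lift"].fillna(False).to_numpy(bool)
    breaks[0] = False
    out = points.drop(columns=[c for c in ("pen_lift", "tract_id") if c in points.columns]).copy()
    out["tract_id"] = np.cumsum(breaks).astype(int)
    return out.reset_index(drop=True)


@dataclass
class DrawingFeatureSet:
    n_tracts: int
    discontinuity_length: float
    tract_discont_perc: float
    total_tract_length: float
    centroid_x: float
    centroid_y: float
    dispersion_from_centroid: float
    dispersion_from_start: float
    time: float
    out_of_trace_length: float | None = None
    out_of_trace_perc: float | None = None
    distance_from_center: float | None = None  # filled at cohort level

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _segment_lengths(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.hypot(np.diff(x), np.diff(y))


def compute_drawing_features(drawing: pd.DataFrame, completion_time: float) -> DrawingFeatureSet:
    """Per-drawing descriptors from a tract-segmented point list.

    Lengths sum consecutive within-tract Euclidean distances; the
    discontinuity length sums the gap between the last point of each tract
    and the first point of the next; dispersions are mean Euclidean
    distances of points from the centroid / from the first point.
    """
    if len(drawing) == 0:
        raise ContractError("drawing has no points")
    x = drawing["x"].to_numpy(float)
    y = drawing["y"].to_numpy(float)
    tract = drawing["tract_id"].to_numpy()

    total = 0.0
    ends: list[tuple[float, float]] = []
    starts: list[tuple[float, float]] = []
    tract_ids = list(dict.fromkeys(tract))
    for tid in tract_ids:
        m = tract == tid
        total += float(_segment_lengths(x[m], y[m]).sum())
        starts.append((x[m][0], y[m][0]))
        ends.append((x[m][-1], y[m][-1]))

    disc = 0.0
    for i in range(len(tract_ids) - 1):
        disc += float(np.hypot(starts[i + 1][0] - ends[i][0], starts[i + 1][1] - ends[i][1]))

    n_tracts = len(tract_ids)
    cx, cy = float(x.mean()), float(y.mean())
    disp_centroid = float(np.mean(np.hypot(x - cx, y - cy)))
    disp_start = float(np.mean(np.hypot(x - x[0], y - y[0])))

    return DrawingFeatureSet(
        n_tracts=n_tracts,
        discontinuity_length=disc,
        tract_discont_perc=(n_tracts - 1) / n_tracts,
        total_tract_length=total,
        centroid_x=cx,
        centroid_y=cy,
        dispersion_from_centroid=disp_centroid,
        dispersion_from_start=disp_start,
        time=float(completion_time),
    )


def compute_trace_features(drawing: pd.DataFrame) -> tuple[float, float]:
    """Out-of-trace length and point fraction for tracing levels.

    The length counts within-tract segments whose *both* endpoints are out
    of trace (boundary-crossing segments are ambiguous and excluded); the
    fraction is the share of points flagged out of trace.
    """
    if "in_trace" not in drawing.columns or drawing["in_trace"].isna().any():
        raise ContractError("tracing features need an in_trace flag on every point")
    out_len = 0.0
    inside = drawing["in_trace"].to_numpy(bool)
    x = drawing["x"].to_numpy(float)
    y = drawing["y"].to_numpy(float)
    tract = drawing["tract_id"].to_numpy()
    for tid in np.unique(tract):
        m = tract == tid
        seg = _segment_lengths(x[m], y[m])
        both_out = (~inside[m][:-1]) & (~inside[m][1:])
        out_len += float(seg[both_out].sum())
    perc = float(np.mean(~inside))
    return out_len, perc


def compute_cohort_spatial_features(
    feature_rows: pd.DataFrame,
    centers: dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Add per-level distance of each centroid from the cohort center.

    ``feature_rows`` is tidy with columns ``subject_id``, ``level``,
    ``centroid_x``, ``centroid_y``.  The cohort center of a level is the
    mean of the subject centroids; precomputed ``centers`` (level ->
    (x, y)) may be supplied, e.g. from a training fold.
    """
    out = feature_rows.copy()
    computed = {}
    dist = np.full(len(out), np.nan)
    for lev, sub in out.groupby("level"):
        if lev in (centers or {}):
            cx, cy = centers[lev]
        else:
            cx, cy = float(sub["centroid_x"].mean()), float(sub["centroid_y"].mean())
        computed[lev] = (cx, cy)
        idx = out["level"] == lev
        dist[idx.to_numpy()] = np.hypot(out.loc[idx, "centroid_x"] - cx, out.loc[idx, "centroid_y"] - cy)
    out["distance_from_center"] = dist
    return out, computed
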