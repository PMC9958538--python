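"""Gaze cleaning, screen partitioning, and eye-tracking metrics."""

import numpy as np
import pandas as pd
import pytest

from scrivo.gaze import (
    FeatureError,
    PanelPartition,
    PartitionError,
    compute_gaze_features,
    filter_confidence,
    fit_and_label_panels,
    scale_by_grade,
    select_challenging_levels,
    standard_distance,
)
from scrivo.levels import (
    PANEL_CENTERS,
    ROLE_CORRECT,
    ROLE_TARGET,
    ROLE_WRONG,
    search_layout,
)


def _frame(confidences):
    n = len(confidences)
    return pd.DataFrame(
        {"t": np.arange(n) * 0.005, "x": 0.5, "y": 0.5, "confidence": confidences}
    )


class TestConfidenceFilter:
    def test_threshold_is_inclusive(self):
        kept = filter_confidence(_frame([0.69, 0.70, 0.71]))
        assert len(kept) == 2 and kept["confidence"].min() == 0.70

    def test_empty_input(self):
        assert len(filter_confidence(_frame([]))) == 0

    def test_matches_brute_force_on_random_confidences(self):
        rng = np.random.default_rng(0)
        conf = rng.random(1000)
        kept = filter_confidence(_frame(conf))
        expected = [c for c in conf if c >= 0.70]
        assert list(kept["confidence"]) == expected

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            filter_confidence(_frame([0.5]), min_conf=1.5)


def _role_partition():
    """Partition with clusters exactly at the canonical panel centers."""
    centers = np.array(list(PANEL_CENTERS.values()))
    positions = dict(enumerate(PANEL_CENTERS))
    roles = {0: ROLE_TARGET, 1: ROLE_WRONG, 2: ROLE_CORRECT, 3: ROLE_WRONG}
    return PanelPartition(centers, positions, roles)


class TestPanelPartition:
    def test_blobs_recover_generating_panels(self, blob_samples, four_panel_layout):
        df = blob_samples(n_per=200, sigma=0.02, seed=1)
        part = fit_and_label_panels(df, four_panel_layout, seed=0)
        clusters = part.assign(df["x"], df["y"])
        assigned_pos = np.array([part.position_of_cluster[c] for c in clusters])
        assert (assigned_pos == df["panel"].to_numpy()).mean() >= 0.99
        # roles come from the layout
        assert part.role_of_cluster[[c for c, p in part.position_of_cluster.items() if p == "left"][0]] == ROLE_TARGET

    def test_identical_points_raise_partition_error(self, four_panel_layout):
        df = pd.DataFrame({"x": [0.5] * 50, "y": [0.5] * 50})
        with pytest.raises(PartitionError):
            fit_and_label_panels(df, four_panel_layout, seed=0)

    def test_mirrored_input_swaps_left_right(self, blob_samples, four_panel_layout):
        df = blob_samples(n_per=150, sigma=0.02, seed=2, mirror=True)
        part = fit_and_label_panels(df, four_panel_layout, seed=0)
        left_cluster = [c for c, p in part.position_of_cluster.items() if p == "left"][0]
        # after mirroring, the option blobs sit on the left; the target role
        # follows the left position label
        assert part.cluster_centers[left_cluster][0] < 0.5
        assert part.role_of_cluster[left_cluster] == ROLE_TARGET
        former_left = df[df["panel"] == "left"]
        clusters = part.assign(former_left["x"], former_left["y"])
        assert all(
            part.position_of_cluster[c].startswith("right") for c in clusters
        )

    def test_single_panel_layout_is_trivial(self):
        df = pd.DataFrame({"x": [0.2, 0.8], "y": [0.3, 0.7]})
        part = fit_and_label_panels(df, search_layout("figure_ground_easy"), seed=0)
        assert len(part.cluster_centers) == 1

    def test_too_few_samples_raise(self, four_panel_layout):
        df = pd.DataFrame({"x": [0.1, 0.9], "y": [0.5, 0.5]})
        with pytest.raises(PartitionError):
            fit_and_label_panels(df, four_panel_layout, seed=0)


class TestGazeFeatures:
    def test_hand_enumerated_bounce_sequence(self):
        """Roles T,O,T,O,O,T contain four target<->option transitions."""
        part = _role_partition()
        seq = ["left", "right_top", "left", "right_top", "right_bottom", "left"]
        xy = np.array([PANEL_CENTERS[p] for p in seq])
        samples = pd.DataFrame(
            {"t": np.arange(6) * 0.005, "x": xy[:, 0], "y": xy[:, 1], "confidence": 1.0}
        )
        feats = compute_gaze_features(samples, samples.rename(columns={"t": "t_start"}).assign(duration=100.0), part)
        assert feats.indecision_gaze == 4
        assert feats.indecision_fix == 4

    def test_single_panel_stream(self):
        part = _role_partition()
        rng = np.random.default_rng(3)
        samples = pd.DataFrame(
            {
                "t": np.arange(50) * 0.005,
                "x": rng.normal(0.25, 0.01, 50),
                "y": rng.normal(0.5, 0.01, 50),
                "confidence": 1.0,
            }
        )
        fix = pd.DataFrame(
            {"t_start": [0.0], "duration": [250.0], "x": [0.25], "y": [0.5], "confidence": [1.0]}
        )
        feats = compute_gaze_features(samples, fix, part)
        assert feats.indecision_gaze == 0
        assert feats.frac_gaze_target == 1.0
        assert feats.dispersion == pytest.approx(
            standard_distance(samples["x"], samples["y"])
        )

    def test_bounce_count_invariant_to_duplicated_samples(self):
        part = _role_partition()
        rng = np.random.default_rng(4)
        seq = rng.choice(list(PANEL_CENTERS), 40)
        xy = np.array([PANEL_CENTERS[p] for p in seq])
        samples = pd.DataFrame(
            {"t": np.arange(40) * 0.01, "x": xy[:, 0], "y": xy[:, 1], "confidence": 1.0}
        )
        doubled = samples.loc[samples.index.repeat(2)].reset_index(drop=True)
        doubled["t"] = np.arange(len(doubled)) * 0.005
        f1 = compute_gaze_features(samples, samples.head(0).rename(columns={"t": "t_start"}).assign(duration=1.0), part)
        f2 = compute_gaze_features(doubled, doubled.head(0).rename(columns={"t": "t_start"}).assign(duration=1.0), part)
        assert f1.indecision_gaze == f2.indecision_gaze

    def test_empty_samples_raise_feature_error(self):
        part = _role_partition()
        empty = pd.DataFrame(columns=["t", "x", "y", "confidence"])
        with pytest.raises(FeatureError):
            compute_gaze_features(empty, empty, part)

    def test_empty_fixations_flagged_missing(self):
        part = _role_partition()
        samples = pd.DataFrame(
            {"t": [0.0, 0.005], "x": [0.25, 0.25], "y": [0.5, 0.5], "confidence": 1.0}
        )
        empty_fix = pd.DataFrame(columns=["t_start", "duration", "x", "y", "confidence"])
        feats = compute_gaze_features(samples, empty_fix, part)
        assert feats.n_fix is None and feats.mean_fix_duration is None

    def test_role_fractions_partition_unity(self, small_cohort):
        spec, records = small_cohort
        from scrivo.gaze import fit_and_label_panels as fit
        from scrivo.levels import default_layouts

        layouts = default_layouts()
        level = "visual_closure_hard"
        for r in records[:5]:
            g = r.gaze[level]
            part = fit(g.samples, layouts[level], seed=0)
            f = compute_gaze_features(g.samples, g.fixations, part)
            assert f.frac_gaze_target + f.frac_gaze_correct + f.frac_gaze_wrong == pytest.approx(1.0)


class TestStandardDistance:
    def test_symmetric_four_point_configuration(self):
        x = [1.0, -1.0, 0.0, 0.0]
        y = [0.0, 0.0, 1.0, -1.0]
        assert standard_distance(x, y) == pytest.approx(1.0)

    def test_translation_invariant_and_scale_equivariant(self):
        rng = np.random.default_rng(6)
        x, y = rng.random(100), rng.random(100)
        d = standard_distance(x, y)
        assert standard_distance(x + 3.5, y - 1.2) == pytest.approx(d)
        assert standard_distance(2.0 * x, 2.0 * y) == pytest.approx(2.0 * d)

    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            x, y = rng.random(20), rng.random(20)
            expected = np.sqrt(
                sum((xi - x.mean()) ** 2 + (yi - y.mean()) ** 2 for xi, yi in zip(x, y))
                / len(x)
            )
            assert standard_distance(x, y) == pytest.approx(expected, abs=1e-12)


class TestGradeScaling:
    def test_groups_become_standard_normal(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(
            {"grade": rng.integers(1, 4, 60), "f": rng.normal(5, 3, 60)}
        )
        scaled = scale_by_grade(df)
        for _, g in scaled.groupby("grade"):
            assert g["f"].mean() == pytest.approx(0.0, abs=1e-9)
            assert g["f"].std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_singleton_group_scales_to_zero(self):
        df = pd.DataFrame({"grade": [1, 2, 2], "f": [7.0, 1.0, 3.0]})
        assert scale_by_grade(df)["f"].iloc[0] == 0.0

    def test_constant_group_scales_to_zero(self):
        df = pd.DataFrame({"grade": [1, 1, 1], "f": [4.0, 4.0, 4.0]})
        assert (scale_by_grade(df)["f"] == 0.0).all()

    def test_matches_brute_force_zscores(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(
            {
                "grade": rng.integers(1, 4, 40),
                "a": rng.normal(0, 2, 40),
                "b": rng.random(40) * 10,
            }
        )
        scaled = scale_by_grade(df)
        for col in ("a", "b"):
            for gr in (1, 2, 3):
                sub = df[df["grade"] == gr][col]
                expected = (sub - sub.mean()) / sub.std(ddof=0)
                got = scaled[scaled["grade"] == gr][col]
                np.testing.assert_allclose(got.to_numpy(), expected.to_numpy(), atol=1e-9)

    def test_nan_values_stay_missing(self):
        df = pd.DataFrame({"grade": [1, 1, 1], "f": [1.0, np.nan, 3.0]})
        scaled = scale_by_grade(df)
        assert np.isnan(scaled["f"].iloc[1]) and not np.isnan(scaled["f"].iloc[0])


class TestChallengingLevelSelection:
    def test_higher_time_variance_ranks_first(self):
        logs = pd.DataFrame(
            {
                "subject_id": list("abc") * 2,
                "level": ["L1"] * 3 + ["L2"] * 3,
                "time": [1, 1, 1, 1, 10, 100],
                "errors": [0, 0, 0, 0, 0, 0],
            }
        )
        assert select_challenging_levels(logs, 1) == ["L2"]

    def test_ties_keep_input_order(self):
        logs = pd.DataFrame(
            {
                "subject_id": list("ab") * 3,
                "level": ["X", "X", "Y", "Y", "Z", "Z"],
                "time": [1, 2] * 3,
                "errors": [0, 0] * 3,
            }
        )
        assert select_challenging_levels(logs, 3) == ["X", "Y", "Z"]

    def test_matches_variance_sort_oracle(self):
        rng = np.random.default_rng(10)
        levels = [f"L{i}" for i in range(8)]
        rows = [
            {"subject_id": f"s{s}", "level": lev, "time": rng.random() * 20, "errors": int(rng.integers(0, 4))}
            for s in range(12)
            for lev in levels
        ]
        logs = pd.DataFrame(rows)
        expected = sorted(
            levels,
            key=lambda lv: -logs[logs["level"] == lv]["time"].var(ddof=1),
        )
        assert select_challenging_levels(logs, 8) == expected
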