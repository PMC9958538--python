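"""Synthetic cohort generator: determinism, moments, and coupling."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from scrivo.levels import LayoutError, LevelLayout, options_layout, search_layout
from scrivo.scoring import ConfigurationError, label_cohort, threshold_and_label
from scrivo.synthetic import (
    CohortSpec,
    LatentSubject,
    bvsco_frame,
    gen_bvsco,
    gen_cohort,
    gen_gaze_stream,
    gen_strokes,
    gen_subjects,
)


def _spec(**kw):
    base = CohortSpec.default(kw.pop("n_subjects", 10), kw.pop("seed", 0))
    return replace(base, **kw)


def _subject(ability=0.0, grade=2, sex="M", sid="S000"):
    return LatentSubject(sid, grade, sex, ability)


class TestDeterminism:
    def test_same_spec_same_seed_reproduces_records(self):
        spec = _spec(n_subjects=3, seed=42)
        a, b = gen_cohort(spec), gen_cohort(spec)
        for ra, rb in zip(a, b):
            assert ra.bvsco == rb.bvsco
            assert ra.game_log == rb.game_log
            assert ra.sus_responses == rb.sus_responses
            for level in ra.gaze:
                pd.testing.assert_frame_equal(ra.gaze[level].samples, rb.gaze[level].samples)
                pd.testing.assert_frame_equal(ra.gaze[level].fixations, rb.gaze[level].fixations)
            for level in ra.drawings:
                pd.testing.assert_frame_equal(ra.drawings[level], rb.drawings[level])

    def test_stream_level_determinism(self):
        spec = _spec(seed=5)
        layout = options_layout("visual_closure_medium")
        g1 = gen_gaze_stream(_subject(0.3), layout, spec, completion_time=6.0)
        g2 = gen_gaze_stream(_subject(0.3), layout, spec, completion_time=6.0)
        pd.testing.assert_frame_equal(g1.samples, g2.samples)
        d1 = gen_strokes(_subject(0.3), "copying_hard", spec, completion_time=12.0)
        d2 = gen_strokes(_subject(0.3), "copying_hard", spec, completion_time=12.0)
        pd.testing.assert_frame_equal(d1, d2)

    def test_different_seeds_differ(self):
        a = gen_cohort(_spec(n_subjects=2, seed=1))
        b = gen_cohort(_spec(n_subjects=2, seed=2))
        assert a[0].bvsco != b[0].bvsco or a[0].game_log != b[0].game_log


class TestSpecValidation:
    def test_bad_grade_probs_named(self):
        with pytest.raises(ConfigurationError, match="grade_probs"):
            gen_cohort(replace(_spec(), grade_probs=(0.5, 0.5, 0.5)))

    def test_missing_effect_family_named(self):
        spec = _spec()
        eff = dict(spec.effect_sizes)
        eff.pop("bvsco")
        with pytest.raises(ConfigurationError, match="bvsco"):
            gen_cohort(replace(spec, effect_sizes=eff))

    def test_nonpositive_ability_sd_rejected(self):
        with pytest.raises(ConfigurationError, match="ability_sd"):
            gen_cohort(replace(_spec(), ability_sd=0.0))


class TestGazeStream:
    def test_zero_switch_rate_means_zero_bounces(self):
        spec = replace(_spec(), gaze_switch_base=0.0)
        g = gen_gaze_stream(_subject(-1.0), options_layout("form_constancy_hard"), spec, 8.0)
        assert g.n_target_option_transitions == 0
        assert len(np.unique(g.panel_seq)) == 1

    def test_missing_target_panel_raises(self):
        layout = LevelLayout.__new__(LevelLayout)  # bypass validation for the error path
        object.__setattr__(layout, "level_id", "broken")
        object.__setattr__(layout, "n_panels", 4)
        object.__setattr__(
            layout,
            "role_by_position",
            {p: "OPTION_WRONG" for p in ("left", "right_top", "right_middle", "right_bottom")},
        )
        with pytest.raises(LayoutError):
            gen_gaze_stream(_subject(), layout, _spec(), 5.0)

    def test_timestamps_strictly_increasing_and_rate_consistent(self):
        g = gen_gaze_stream(_subject(0.5), options_layout("form_constancy_easy"), _spec(), 6.0)
        t = g.samples["t"].to_numpy()
        assert (np.diff(t) > 0).all()
        # within fixations samples arrive at the tracker rate
        assert np.median(np.diff(t)) == pytest.approx(1 / 200, rel=1e-6)

    def test_low_confidence_fraction_controlled(self):
        spec = replace(_spec(), low_conf_frac=0.3)
        g = gen_gaze_stream(_subject(), options_layout("form_constancy_easy"), spec, 30.0)
        frac = (g.samples["confidence"] < 0.70).mean()
        assert abs(frac - 0.3) < 0.05

    def test_mean_transition_count_matches_markov_expectation(self):
        """Empirical mean target<->option transition count agrees with the
        two-state lumped chain's analytic expectation within 3 SE."""
        spec = _spec(seed=21)  # default effects; ability 0 subject
        layout = options_layout("masked_form_constancy_medium")
        diffs = []
        for i in range(400):
            g = gen_gaze_stream(_subject(0.0, sid=f"S{i:03d}"), layout, spec, 5.0)
            n = len(g.fixations)
            p, q = g.p_switch, g.p_return_target
            # occupancy iteration of the lumped {target, option} chain
            p_t, expected = 1.0, 0.0
            for _ in range(n - 1):
                expected += p_t * p + (1 - p_t) * p * q
                p_t = p_t * (1 - p) + (1 - p_t) * p * q
            diffs.append(g.n_target_option_transitions - expected)
        diffs = np.asarray(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < 3 * se + 1e-12


class TestStrokes:
    def test_degenerate_limit_recovers_template(self):
        """No ability effects, no extra pen lifts, vanishing jitter: the
        drawing is the template (its own strokes only, centroid preserved)."""
        spec = replace(
            CohortSpec.default(5, 3, effect_scale=0.0),
            pen_lift_base=0.0,
            noise_sd={**CohortSpec.default(5, 3).noise_sd, "drawing": 0.0},
        )
        from scrivo.levels import drawing_template

        d = gen_strokes(_subject(0.0), "copying_easy", spec, 10.0)
        template = drawing_template("copying_easy")
        assert d["tract_id"].nunique() == len(template)
        tc = np.vstack(template).mean(axis=0)
        assert np.hypot(d["x"].mean() - tc[0], d["y"].mean() - tc[1]) < 0.03

    def test_centroid_x_increases_with_ability(self):
        """Positive placement effect: regression slope of centroid x on
        ability is positive (at-risk children draw to the lower left)."""
        spec = _spec(seed=31)
        rng = np.random.default_rng(0)
        abilities = rng.normal(0, 1, 300)
        cx = []
        for i, a in enumerate(abilities):
            d = gen_strokes(_subject(a, sid=f"S{i:03d}"), "copying_medium", spec, 12.0)
            cx.append(d["x"].mean())
        slope = np.polyfit(abilities, cx, 1)[0]
        assert slope > 0.02

    def test_pen_lift_rate_decreases_with_ability(self):
        spec = _spec(seed=32)
        n_tracts = {a: [] for a in (-2.0, 2.0)}
        for a in n_tracts:
            for i in range(80):
                d = gen_strokes(_subject(a, sid=f"T{i:03d}"), "tracing_hard", spec, 15.0)
                n_tracts[a].append(d["tract_id"].nunique())
        assert np.mean(n_tracts[-2.0]) > np.mean(n_tracts[2.0])

    def test_tracing_in_trace_flags_present_and_informative(self):
        spec = _spec(seed=33)
        d_low = gen_strokes(_subject(-2.5, sid="L"), "tracing_medium", spec, 12.0)
        d_high = gen_strokes(_subject(2.5, sid="H"), "tracing_medium", spec, 12.0)
        assert "in_trace" in d_low.columns
        assert (~d_low["in_trace"]).mean() >= (~d_high["in_trace"]).mean()


class TestBVSCO:
    def test_zero_ability_zero_noise_hits_normative_means(self):
        spec = replace(
            _spec(),
            noise_sd={**_spec().noise_sd, "bvsco": 0.0},
            sex_effect_bvsco=0.0,
        )
        for grade in (1, 2, 3):
            r = gen_bvsco(_subject(0.0, grade=grade), spec)
            assert r.counts == tuple(
                int(round(spec.norms.mean(grade, e))) for e in (1, 2, 3)
            )

    def test_very_low_ability_forces_at_risk(self):
        """Ability four SDs below average with a unit (one-norm-SD) effect
        puts every exercise under mean - 2 SD."""
        spec = replace(
            _spec(),
            effect_sizes={**_spec().effect_sizes, "bvsco": 8.0},
            noise_sd={**_spec().noise_sd, "bvsco": 0.5},
            sex_effect_bvsco=0.0,
        )
        r = gen_bvsco(_subject(-4.0), spec)
        lab = threshold_and_label(r, spec.norms)
        assert lab.per_exercise == (True, True, True) and lab.at_risk

    def test_count_sd_matches_noise_sd(self):
        spec = replace(_spec(seed=41), sex_effect_bvsco=0.0)
        counts = np.array(
            [gen_bvsco(_subject(0.0, sid=f"S{i:04d}"), spec).counts for i in range(2000)]
        )
        for e in range(3):
            sd = counts[:, e].std(ddof=1)
            assert abs(sd - spec.noise_sd["bvsco"]) / spec.noise_sd["bvsco"] < 0.05

    def test_missing_grade_in_norms_raises(self):
        with pytest.raises(ConfigurationError):
            gen_bvsco(LatentSubject("X", 4, "M", 0.0), _spec())


class TestCohortCoupling:
    def test_null_effects_decouple_ability_from_features(self):
        """With all effect sizes zero, ability and gaze bouncing are
        uncorrelated up to sampling error."""
        spec = CohortSpec.default(1, seed=51, effect_scale=0.0)
        layout = options_layout("masked_form_constancy_hard")
        rng = np.random.default_rng(1)
        abilities = rng.normal(0, 1, 200)
        bounces = [
            gen_gaze_stream(
                _subject(a, sid=f"N{i:03d}"), layout, spec, 5.0
            ).n_target_option_transitions
            for i, a in enumerate(abilities)
        ]
        assert abs(np.corrcoef(abilities, bounces)[0, 1]) < 0.2

    def test_strong_bounce_effect_couples_label_and_bounces(self):
        """A strong ability->bounce effect makes the derived risk label and
        the bounce count clearly dependent (point-biserial r > 0.5)."""
        spec = _spec(n_subjects=200, seed=52)
        spec = replace(spec, effect_sizes={**spec.effect_sizes, "gaze_bounce": 2.0})
        subjects = gen_subjects(spec)
        layout = options_layout("masked_form_constancy_hard")
        bounce = [
            gen_gaze_stream(s, layout, spec, 6.0).n_target_option_transitions
            for s in subjects
        ]
        risk = [
            threshold_and_label(gen_bvsco(s, spec), spec.norms).at_risk for s in subjects
        ]
        r = np.corrcoef(np.asarray(risk, float), np.asarray(bounce, float))[0, 1]
        assert r > 0.5

    def test_grade_distribution_and_record_completeness(self, small_cohort):
        spec, records = small_cohort
        assert len(records) == spec.n_subjects
        for r in records:
            assert len(r.game_log) == 18
            assert len(r.gaze) == 12
            assert len(r.drawings) == 6
            assert r.grade in (1, 2, 3)

    def test_label_prevalence_near_study_rate(self):
        """Default conditions produce an at-risk share near the 40% range
        the screening rule is calibrated to emulate."""
        spec = CohortSpec.default(300, seed=53)
        labels = label_cohort(
            bvsco_frame([_r for _r in _bvsco_only(spec)]), spec.norms
        )
        share = labels["at_risk"].mean()
        assert 0.2 < share < 0.55


def _bvsco_only(spec):
    """Light-weight records carrying only BVSCO results (for prevalence)."""
    from types import SimpleNamespace

    for s in gen_subjects(spec):
        yield SimpleNamespace(subject_id=s.subject_id, grade=s.grade, bvsco=gen_bvsco(s, spec))
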