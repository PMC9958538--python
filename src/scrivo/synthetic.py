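"""Synthetic cohort generator for the screening battery.

A single latent handwriting-ability factor (zero mean, configurable SD)
drives every modality: game completion times and errors, gaze behavior
(panel bouncing, target fraction, fixation duration), drawing morphology
(scale, placement, pen-lift discontinuity, copying time) and the BVSCO-2
grapheme counts from which the at-risk label is derived by the normative
rule — the label is never assigned directly.

Each modality additionally carries a per-subject disposition factor
(a test-retest-style nuisance shared by all of that modality's features),
so no modality observes ability noiselessly, and per-feature measurement
noise on top.  Level "salience" weights encode that only the harder levels
discriminate strongly between children, mirroring the variance-based level
selection the analysis performs.

Everything is deterministic under a fixed seed at cohort, subject and
stream granularity.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import levels as lv
from .scoring import BVSCOResult, ConfigurationError, NormativeTable, sus_score

# ---------------------------------------------------------------------------
# specification
# ---------------------------------------------------------------------------

EFFECT_FAMILIES = (
    "game_time",
    "game_errors",
    "gaze_bounce",
    "gaze_target_frac",
    "fix_duration",
    "drawing_scale",
    "drawing_offset",
    "discontinuity",
    "copy_time",
    "bvsco",
)

#: standardized-ish default effects of ability on each feature family,
#: in that family's units per ability SD
DEFAULT_EFFECTS = {
    "game_time": -3.0,  # s: weaker children take longer
    "game_errors": -0.4,
    "gaze_bounce": 0.8,  # logit units: weaker children bounce more
    "gaze_target_frac": 0.5,  # logit units on return-to-target probability
    "fix_duration": -0.12,  # log-s: weaker children fixate longer
    "drawing_scale": 0.08,  # log-scale: at-risk children draw smaller
    "drawing_offset": 0.04,  # screen units: at-risk children draw lower-left
    "discontinuity": 0.4,  # log pen-lift rate: at-risk children lift more
    "copy_time": 2.5,  # s: stronger children take longer to copy
    "bvsco": 24.0,  # graphemes/min per ability SD
    "trace_tremor": 0.3,  # log tremor amplitude while tracing (falls with ability)
}

DEFAULT_NOISE = {
    "game_time": 3.0,  # s, scaled up with difficulty
    "game_errors": 0.45,
    "fix_duration": 0.35,  # lognormal sigma
    "gaze_jitter": 0.015,  # within-fixation sample scatter (screen units)
    "fixation_scatter": 0.03,  # fixation placement around the panel center
    "drawing": 0.01,  # per-point pen jitter
    "copy_time": 4.0,  # s
    "bvsco": 8.0,  # graphemes/min
}

#: per-subject modality dispositions (ability-scale SD).  Zero by default:
#: feature families are then conditionally independent given ability, the
#: generator's core contract.  Positive values add a shared test-retest-style
#: nuisance per modality (an optional realism knob for robustness studies).
DEFAULT_MODALITY_SD = {"game": 0.0, "eye": 0.0, "drawing": 0.0}

_BASE_TIME = {"easy": 6.0, "medium": 9.0, "hard": 12.0}
_BASE_COPY_TIME = {"easy": 10.0, "medium": 15.0, "hard": 20.0}
_BASE_ERRORS = {"easy": 0.4, "medium": 0.6, "hard": 0.8}
_TIME_NOISE_MULT = {"easy": 0.6, "medium": 1.0, "hard": 1.3}
_GRADE_TIME_FACTOR = {1: 1.15, 2: 1.0, 3: 0.9}
_LIFT_RATE_MULT = {"easy": 0.6, "medium": 1.0, "hard": 1.4}

#: how strongly each level's time/errors load on ability (harder levels
#: discriminate more, as the variance-based selection assumes)
DEFAULT_SALIENCE = {}
for _g, _w in (
    ("form_constancy", (0.3, 0.5, 0.6)),
    ("masked_form_constancy", (0.5, 1.0, 1.2)),
    ("visual_closure", (0.4, 0.8, 1.0)),
    ("figure_ground", (0.5, 1.0, 1.15)),
):
    for _d, _s in zip(lv.DIFFICULTIES, _w):
        DEFAULT_SALIENCE[lv.level_id(_g, _d)] = _s


@dataclass(frozen=True)
class CohortSpec:
    """All knobs of the synthetic cohort."""

    n_subjects: int = 53
    grade_probs: tuple = (15 / 53, 22 / 53, 16 / 53)
    ability_sd: float = 1.0
    effect_sizes: dict = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_NOISE))
    modality_sd: dict = field(default_factory=lambda: dict(DEFAULT_MODALITY_SD))
    level_salience: dict = field(default_factory=lambda: dict(DEFAULT_SALIENCE))
    norms: NormativeTable = field(default_factory=NormativeTable.default_synthetic)
    seed: int = 0
    gaze_switch_base: float = 0.35  # baseline panel-switch probability
    target_return_base: float = 0.55  # baseline switch-to-target probability
    low_conf_frac: float = 0.12  # share of samples below the 0.70 cutoff
    mean_fix_duration_s: float = 0.28
    sample_rate_hz: float = 200.0
    pen_lift_base: float = 2.0  # mean extra pen lifts per drawing
    trace_tol: float = 0.025  # in-trace distance tolerance
    sex_effect_bvsco: float = 2.5  # graphemes/min, +F / -M
    sus_mean: float = 89.4
    sus_sd: float = 9.6
    missing_fixation_rate: float = 0.0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if abs(sum(self.grade_probs) - 1.0) > 1e-9 or len(self.grade_probs) != 3:
            raise ConfigurationError("grade_probs must be 3 probabilities summing to 1")
        if self.ability_sd <= 0:
            raise ConfigurationError("ability_sd must be positive")
        for fam in EFFECT_FAMILIES:
            if fam not in self.effect_sizes:
                raise ConfigurationError(f"effect_sizes missing family {fam!r}")
        for fam, sd in self.noise_sd.items():
            if sd < 0:
                raise ConfigurationError(f"noise_sd[{fam!r}] must be >= 0")
        if not 0.0 <= self.gaze_switch_base <= 1.0:
            raise ConfigurationError("gaze_switch_base must be a probability")
        if not 0.0 <= self.low_conf_frac <= 1.0:
            raise ConfigurationError("low_conf_frac must be a probability")

    def scaled(self, effect_scale: float) -> "CohortSpec":
        """Spec with every ability effect multiplied by ``effect_scale``."""
        eff = {k: v * effect_scale for k, v in self.effect_sizes.items()}
        return replace(self, effect_sizes=eff)

    @classmethod
    def default(cls, n_subjects: int = 53, seed: int = 0, effect_scale: float = 1.0) -> "CohortSpec":
        return cls(n_subjects=n_subjects, seed=seed).scaled(effect_scale)

    @classmethod
    def null(cls, n_subjects: int = 200, seed: int = 0) -> "CohortSpec":
        """Null-calibration spec: no ability effects, balanced label split.

        With all effects zero, the grapheme counts are pure noise around the
        normative means; the BVSCO noise SD is set analytically so that the
        mean - 2*SD rule flags each exercise with probability
        1 - 0.5**(1/3), i.e. the at-risk label splits 50/50 in expectation.
        """
        spec = cls(n_subjects=n_subjects, seed=seed).scaled(0.0)
        q = 1.0 - 0.5 ** (1.0 / 3.0)
        norm_sd = spec.norms.sd(1, 1)
        noise = dict(spec.noise_sd)
        noise["bvsco"] = float(2.0 * norm_sd / -norm.ppf(q))
        return replace(spec, noise_sd=noise)


@dataclass(frozen=True)
class LatentSubject:
    subject_id: str
    grade: int
    sex: str
    ability: float


@dataclass
class SimulatedGaze:
    """A generated gaze stream plus its generating ground truth."""

    samples: pd.DataFrame
    fixations: pd.DataFrame
    panel_seq: np.ndarray | None = None
    n_target_option_transitions: int | None = None
    p_switch: float | None = None
    p_return_target: float | None = None


@dataclass
class SubjectRecord:
    subject_id: str
    grade: int
    sex: str
    ability: float
    game_log: dict  # level -> {"time": s, "errors": int | None}
    gaze: dict  # level -> SimulatedGaze
    drawings: dict  # level -> DataFrame (t, x, y, tract_id[, in_trace])
    bvsco: BVSCOResult
    sus_responses: list
    questionnaire: dict


# ---------------------------------------------------------------------------
# deterministic per-entity randomness
# ---------------------------------------------------------------------------

def _rng(seed: int, *tokens) -> np.random.Generator:
    """Independent generator keyed by the spec seed and string/int tokens."""
    entropy = [seed & 0x7FFFFFFF]
    for tok in tokens:
        entropy.append(zlib.crc32(str(tok).encode()))
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _sigmoid(z: float) -> float:
    return 1.0 / (1.0 + np.exp(-z))


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


# ---------------------------------------------------------------------------
# per-modality generators
# ---------------------------------------------------------------------------

def _modality_factors(subject: LatentSubject, spec: CohortSpec) -> dict:
    rng = _rng(spec.seed, subject.subject_id, "modality")
    return {
        mod: float(rng.normal(0.0, sd)) for mod, sd in spec.modality_sd.items()
    }


def game_completion_time(subject: LatentSubject, level: str, spec: CohortSpec) -> float:
    """Deterministic (seeded) completion time; shared by the game log and
    the gaze stream so eye and game data stay coupled."""
    rng = _rng(spec.seed, subject.subject_id, level, "time")
    mods = _modality_factors(subject, spec)
    game = level.rsplit("_", 1)[0]
    diff = level.rsplit("_", 1)[1]
    if game in ("copying", "tracing"):
        mu = _BASE_COPY_TIME[diff] + spec.effect_sizes["copy_time"] * (
            subject.ability + mods["drawing"]
        )
        t = mu + rng.normal(0.0, spec.noise_sd["copy_time"])
        return float(max(2.0, t))
    sal = spec.level_salience.get(level, 1.0)
    mu = _BASE_TIME[diff] * _GRADE_TIME_FACTOR[subject.grade] + sal * spec.effect_sizes[
        "game_time"
    ] * (subject.ability + mods["game"])
    t = mu + rng.normal(0.0, spec.noise_sd["game_time"] * _TIME_NOISE_MULT[diff])
    return float(max(0.8, t))


def game_errors(subject: LatentSubject, level: str, spec: CohortSpec) -> int:
    rng = _rng(spec.seed, subject.subject_id, level, "errors")
    mods = _modality_factors(subject, spec)
    diff = level.rsplit("_", 1)[1]
    sal = spec.level_salience.get(level, 1.0)
    mu = _BASE_ERRORS[diff] + sal * spec.effect_sizes["game_errors"] * (
        subject.ability + mods["game"]
    )
    e = mu + rng.normal(0.0, spec.noise_sd["game_errors"])
    return int(max(0, round(e)))


def _confidences(rng: np.random.Generator, n: int, spec: CohortSpec) -> np.ndarray:
    low = rng.random(n) < spec.low_conf_frac
    conf = rng.uniform(0.70, 1.0, n)
    conf[low] = rng.uniform(0.15, 0.699, low.sum())
    return conf


def gen_gaze_stream(
    subject: LatentSubject,
    layout: lv.LevelLayout,
    spec: CohortSpec,
    completion_time: float | None = None,
) -> SimulatedGaze:
    """Simulate one level's gaze stream as a renewal process of fixations.

    Fixations sit at panel centers plus isotropic Gaussian scatter; the
    panel-visit sequence is a Markov chain whose probability of a
    target<->option transition rises as ability falls.  Gaze samples are
    emitted at the tracker rate within each fixation; a spec-controlled
    fraction of confidences falls below the 0.70 cleaning cutoff.
    """
    if layout.n_panels == 4 and lv.ROLE_TARGET not in layout.role_by_position.values():
        raise lv.LayoutError(f"{layout.level_id}: no target panel")
    if completion_time is None:
        completion_time = game_completion_time(subject, layout.level_id, spec)
    rng = _rng(spec.seed, subject.subject_id, layout.level_id, "gaze")
    mods = _modality_factors(subject, spec)
    a_eye = subject.ability + mods["eye"]

    # renewal process of fixation durations until the level ends
    durations = []
    total = 0.0
    saccade_gap = 0.03
    mu_log = np.log(spec.mean_fix_duration_s) + spec.effect_sizes["fix_duration"] * a_eye
    while total < completion_time and len(durations) < 600:
        d = float(np.exp(rng.normal(mu_log, spec.noise_sd["fix_duration"])))
        d = min(max(d, 0.04), 2.0)
        durations.append(d)
        total += d + saccade_gap
    n_fix = max(len(durations), 1)
    durations = np.asarray(durations[:n_fix])

    if layout.n_panels == 4:
        if spec.gaze_switch_base <= 0.0:
            p_switch = 0.0
        else:
            p_switch = _sigmoid(
                _logit(spec.gaze_switch_base) - spec.effect_sizes["gaze_bounce"] * a_eye
            )
        p_ret = _sigmoid(
            _logit(spec.target_return_base) + spec.effect_sizes["gaze_target_frac"] * a_eye
        )
        positions = list(lv.PANEL_POSITIONS)
        target_idx = positions.index(
            next(p for p, r in layout.role_by_position.items() if r == lv.ROLE_TARGET)
        )
        option_idx = [i for i in range(4) if i != target_idx]
        seq = np.empty(n_fix, dtype=int)
        state = target_idx  # the child inspects the reference first
        n_bounce = 0
        for i in range(n_fix):
            seq[i] = state
            if i == n_fix - 1:
                break
            if rng.random() < p_switch:
                if state == target_idx:
                    state = option_idx[rng.integers(3)]
                    n_bounce += 1
                else:
                    if rng.random() < p_ret:
                        state = target_idx
                        n_bounce += 1
                    else:
                        others = [o for o in option_idx if o != state]
                        state = others[rng.integers(2)]
        centers = np.array([lv.PANEL_CENTERS[p] for p in positions])
        fix_xy = centers[seq] + rng.normal(0.0, spec.noise_sd["fixation_scatter"], (n_fix, 2))
    else:
        p_switch = p_ret = None
        n_bounce = None
        seq = None
        fix_xy = np.column_stack(
            [
                np.clip(rng.normal(0.5, 0.18, n_fix), 0.03, 0.97),
                np.clip(rng.normal(0.5, 0.18, n_fix), 0.03, 0.97),
            ]
        )

    t_start = np.concatenate([[0.0], np.cumsum(durations + saccade_gap)[:-1]])
    fixations = pd.DataFrame(
        {
            "t_start": t_start,
            "duration": durations * 1000.0,  # ms
            "x": fix_xy[:, 0],
            "y": fix_xy[:, 1],
            "confidence": _confidences(rng, n_fix, spec),
        }
    )

    # 200 Hz gaze samples within each fixation
    step = 1.0 / spec.sample_rate_hz
    n_samp = np.maximum(1, np.round(durations / step).astype(int))
    fix_of_sample = np.repeat(np.arange(n_fix), n_samp)
    within = np.concatenate([np.arange(k) * step for k in n_samp])
    ts = t_start[fix_of_sample] + within
    jit = rng.normal(0.0, spec.noise_sd["gaze_jitter"], (len(ts), 2))
    samples = pd.DataFrame(
        {
            "t": ts,
            "x": fix_xy[fix_of_sample, 0] + jit[:, 0],
            "y": fix_xy[fix_of_sample, 1] + jit[:, 1],
            "confidence": _confidences(rng, len(ts), spec),
        }
    )
    # strictly increasing timestamps by construction (renewal + saccade gap)
    return SimulatedGaze(
        samples=samples,
        fixations=fixations,
        panel_seq=seq,
        n_target_option_transitions=n_bounce,
        p_switch=p_switch,
        p_return_target=p_ret,
    )


def _point_to_polyline_dist(pts: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Min distance from each point to any segment of a polyline."""
    a = poly[:-1][None, :, :]  # (1, m, 2)
    b = poly[1:][None, :, :]
    p = pts[:, None, :]  # (n, 1, 2)
    ab = b - a
    denom = (ab**2).sum(axis=2)
    denom[denom == 0] = 1e-12
    t = ((p - a) * ab).sum(axis=2) / denom
    t = np.clip(t, 0.0, 1.0)
    proj = a + t[:, :, None] * ab
    d = np.sqrt(((p - proj) ** 2).sum(axis=2))
    return d.min(axis=1)


def _resample_polyline(poly: np.ndarray, step: float = 0.01) -> np.ndarray:
    seg = np.hypot(*np.diff(poly, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if cum[-1] <= 0:
        return poly[[0]]
    s = np.arange(0.0, cum[-1], step)
    s = np.append(s, cum[-1])
    x = np.interp(s, cum, poly[:, 0])
    y = np.interp(s, cum, poly[:, 1])
    return np.column_stack([x, y])


def _smooth_noise(rng: np.random.Generator, n: int, sd: float, width: int = 9) -> np.ndarray:
    """Temporally correlated jitter (hand tremor), unit-variance smoothed
    white noise scaled to ``sd`` — smooth so it wobbles the pen path without
    inflating arc length the way white noise would."""
    if n == 0 or sd == 0:
        return np.zeros(n)
    from scipy.ndimage import gaussian_filter1d

    raw = rng.normal(0.0, 1.0, n + 2 * width)
    sm = gaussian_filter1d(raw, width)[width : width + n]
    s = sm.std()
    return sm / s * sd if s > 0 else np.zeros(n)


PEN_SAMPLE_HZ = 60.0


def gen_strokes(
    subject: LatentSubject,
    level: str,
    spec: CohortSpec,
    completion_time: float | None = None,
) -> pd.DataFrame:
    """Simulate a copying or tracing drawing.

    The level template is scaled by exp(scale_effect * ability), translated
    towards the lower-left for weaker children, split into extra tracts by a
    Poisson pen-lift process whose rate falls with ability (the pen skips a
    little path while airborne, leaving a spatial gap), then sampled at the
    tablet rate along the path with smooth tremor jitter.  Tracing levels
    get an ``in_trace`` flag from the distance to the reference template.
    """
    strokes = lv.drawing_template(level)
    if completion_time is None:
        completion_time = game_completion_time(subject, level, spec)
    rng = _rng(spec.seed, subject.subject_id, level, "strokes")
    mods = _modality_factors(subject, spec)
    a_draw = subject.ability + mods["drawing"]
    tracing = level.startswith("tracing")

    # tracing is anchored to the visible reference: scale/placement effects
    # are strongly damped and the ability signal moves into tremor amplitude
    damp = 0.15 if tracing else 1.0
    s = float(np.exp(damp * spec.effect_sizes["drawing_scale"] * a_draw))
    s = min(max(s, 0.2), 4.0)
    off = spec.effect_sizes["drawing_offset"] * a_draw * damp
    shift = np.array([off, 0.6 * off]) + rng.normal(0.0, 0.008 * damp, 2)
    tremor_sd = spec.noise_sd["drawing"]
    if tracing:
        tremor_sd *= float(
            np.clip(np.exp(-spec.effect_sizes.get("trace_tremor", 0.0) * a_draw), 0.3, 3.0)
        )

    template_centroid = np.vstack(strokes).mean(axis=0)
    lift_rate = spec.pen_lift_base * _LIFT_RATE_MULT[level.rsplit("_", 1)[1]] * float(
        np.exp(-spec.effect_sizes["discontinuity"] * a_draw)
    )
    n_extra = int(rng.poisson(lift_rate)) if lift_rate > 0 else 0

    # transformed template polylines, finely resampled
    polys = []
    for stroke in strokes:
        p = (stroke - template_centroid) * s + template_centroid + shift
        polys.append(_resample_polyline(p, step=0.004))

    # extra pen lifts: cut a polyline and skip a short stretch of path
    for _ in range(n_extra):
        lengths = np.array([len(p) for p in polys], float)
        if lengths.sum() < 30:
            break
        which = int(rng.choice(len(polys), p=lengths / lengths.sum()))
        p = polys[which]
        if len(p) < 12:
            continue
        i = int(rng.integers(4, len(p) - 6))
        k = int(rng.integers(1, 4))  # skipped path points -> spatial gap
        polys[which : which + 1] = [p[:i], p[i + k :]]

    # sample each tract at the tablet rate, time proportional to arc length
    tract_polys = [p for p in polys if len(p) >= 2]
    arc = [float(np.hypot(*np.diff(p, axis=0).T).sum()) for p in tract_polys]
    total_len = max(sum(arc), 1e-9)
    draw_time = max(completion_time - 0.3 * (len(tract_polys) - 1), 1.0)

    frames, t0 = [], 0.0
    for tid, (p, L) in enumerate(zip(tract_polys, arc)):
        T = max(draw_time * L / total_len, 2.0 / PEN_SAMPLE_HZ)
        n = max(2, int(round(T * PEN_SAMPLE_HZ)))
        cum = np.concatenate([[0.0], np.cumsum(np.hypot(*np.diff(p, axis=0).T))])
        si = np.linspace(0.0, cum[-1], n)
        x = np.interp(si, cum, p[:, 0]) + _smooth_noise(rng, n, tremor_sd)
        y = np.interp(si, cum, p[:, 1]) + _smooth_noise(rng, n, tremor_sd)
        t = t0 + np.arange(n) / PEN_SAMPLE_HZ
        frames.append(pd.DataFrame({"t": t, "x": x, "y": y, "tract_id": tid}))
        t0 = t[-1] + 0.3  # pen-up pause between tracts
    out = pd.concat(frames, ignore_index=True)

    if tracing:
        pts = out[["x", "y"]].to_numpy()
        d = np.full(len(pts), np.inf)
        for stroke in strokes:
            d = np.minimum(d, _point_to_polyline_dist(pts, stroke))
        out["in_trace"] = d <= spec.trace_tol
    return out


def gen_bvsco(subject: LatentSubject, spec: CohortSpec) -> BVSCOResult:
    """Grapheme counts: Normal around the grade's normative mean, shifted by
    ability (and a small sex effect), rounded to non-negative integers."""
    rng = _rng(spec.seed, subject.subject_id, "bvsco")
    sex_shift = spec.sex_effect_bvsco * (1.0 if subject.sex == "F" else -1.0)
    counts = []
    for e in (1, 2, 3):
        mu = (
            spec.norms.mean(subject.grade, e)
            + spec.effect_sizes["bvsco"] * subject.ability
            + sex_shift
        )
        c = mu + rng.normal(0.0, spec.noise_sd["bvsco"])
        counts.append(int(max(0, round(c))))
    return BVSCOResult(grade=subject.grade, counts=tuple(counts))


def gen_sus_responses(subject: LatentSubject, spec: CohortSpec) -> list:
    """Ten 1-5 items whose SUS transform lands near the target usability."""
    rng = _rng(spec.seed, subject.subject_id, "sus")
    target = float(np.clip(rng.normal(spec.sus_mean, spec.sus_sd), 0.0, 100.0))
    p = target / 100.0
    resp = []
    for i in range(1, 11):
        b = int(rng.binomial(4, p))
        resp.append(1 + b if i % 2 == 1 else 5 - b)
    return resp


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def gen_subjects(spec: CohortSpec) -> list:
    rng = _rng(spec.seed, "cohort")
    grades = rng.choice([1, 2, 3], size=spec.n_subjects, p=list(spec.grade_probs))
    sexes = rng.choice(["M", "F"], size=spec.n_subjects)
    abilities = rng.normal(0.0, spec.ability_sd, spec.n_subjects)
    return [
        LatentSubject(f"S{i:03d}", int(grades[i]), str(sexes[i]), float(abilities[i]))
        for i in range(spec.n_subjects)
    ]


def gen_cohort(spec: CohortSpec) -> list:
    """Generate the full cohort of subject records.

    Every level of the battery gets a game-log entry; gaze streams are
    generated for the non-drawing games, stroke logs for copying and
    tracing, and BVSCO-2 counts for all subjects.
    """
    spec.validate()
    layouts = lv.default_layouts()
    records = []
    for subject in gen_subjects(spec):
        game_log, gaze, drawings = {}, {}, {}
        for level in lv.all_levels():
            game = level.rsplit("_", 1)[0]
            kind = lv.GAMES[game]
            time = game_completion_time(subject, level, spec)
            errors = game_errors(subject, level, spec) if kind in ("options", "search") else None
            game_log[level] = {"time": time, "errors": errors}
            if kind in ("options", "search"):
                gaze[level] = gen_gaze_stream(subject, layouts[level], spec, time)
            else:
                drawings[level] = gen_strokes(subject, level, spec, time)
        if spec.missing_fixation_rate > 0.0:
            miss_rng = _rng(spec.seed, subject.subject_id, "missing")
            if miss_rng.random() < spec.missing_fixation_rate:
                lev = list(gaze)[int(miss_rng.integers(len(gaze)))]
                gaze[lev].fixations = gaze[lev].fixations.iloc[0:0]
        age = 5.8 + subject.grade + float(_rng(spec.seed, subject.subject_id, "age").uniform(0, 1))
        sus = gen_sus_responses(subject, spec)
        records.append(
            SubjectRecord(
                subject_id=subject.subject_id,
                grade=subject.grade,
                sex=subject.sex,
                ability=subject.ability,
                game_log=game_log,
                gaze=gaze,
                drawings=drawings,
                bvsco=gen_bvsco(subject, spec),
                sus_responses=sus,
                questionnaire={"age": round(age, 2), "sex": subject.sex, "sus": sus_score(sus)},
            )
        )
    return records


def bvsco_frame(records: list) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "grade": [r.grade for r in records],
            "c1": [r.bvsco.counts[0] for r in records],
            "c2": [r.bvsco.counts[1] for r in records],
            "c3": [r.bvsco.counts[2] for r in records],
        }
    )


def write_cohort(records: list, outdir, spec: CohortSpec, dialect=None) -> None:
    """Write one directory per subject plus cohort-level norms and manifest."""
    from pathlib import Path

    from .io import GazeExportDialect, write_gaze_exports

    dialect = dialect or GazeExportDialect()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec.norms.to_csv(outdir / "norms.csv")
    manifest = {
        "n_subjects": len(records),
        "seed": spec.seed,
        "synthetic": True,
        "latent_ability": {r.subject_id: r.ability for r in records},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    for r in records:
        sdir = outdir / r.subject_id
        sdir.mkdir(exist_ok=True)
        (sdir / "game_log.json").write_text(json.dumps(r.game_log, indent=1, sort_keys=True))
        (sdir / "questionnaire.json").write_text(
            json.dumps({**r.questionnaire, "sus_responses": r.sus_responses}, sort_keys=True)
        )
        pd.DataFrame(
            [
                {
                    "subject_id": r.subject_id,
                    "grade": r.grade,
                    "c1": r.bvsco.counts[0],
                    "c2": r.bvsco.counts[1],
                    "c3": r.bvsco.counts[2],
                }
            ]
        ).to_csv(sdir / "bvsco.csv", index=False)
        for level, g in r.gaze.items():
            ldir = sdir / "levels" / level
            ldir.mkdir(parents=True, exist_ok=True)
            write_gaze_exports(g.samples, g.fixations, ldir, dialect)
        for level, d in r.drawings.items():
            d.to_csv(sdir / f"strokes_{level}.csv", index=False)
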