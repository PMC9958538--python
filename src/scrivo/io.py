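"""Readers and writers for the eye-tracker export dialect and cohort files.

Gaze and fixation files follow the column dialect of the tracker player's
CSV exports (``gaze_timestamp``, ``norm_pos_x``, ``norm_pos_y``,
``confidence``; fixations add ``start_timestamp`` and ``duration``).  The
dialect is configurable because column names vary across tracker software
versions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .gaze import FIXATION_COLUMNS, GAZE_COLUMNS

log = logging.getLogger("scrivo")


class DialectError(ValueError):
    """An export file does not match the configured column dialect."""


@dataclass(frozen=True)
class GazeExportDialect:
    timestamp: str = "gaze_timestamp"
    x: str = "norm_pos_x"
    y: str = "norm_pos_y"
    confidence: str = "confidence"
    fix_start: str = "start_timestamp"
    fix_duration: str = "duration"

    def gaze_map(self) -> dict:
        return {self.timestamp: "t", self.x: "x", self.y: "y", self.confidence: "confidence"}

    def fixation_map(self) -> dict:
        return {
            self.fix_start: "t_start",
            self.fix_duration: "duration",
            self.x: "x",
            self.y: "y",
            self.confidence: "confidence",
        }


def _read_export(path, colmap: dict, sort_col: str) -> tuple[pd.DataFrame, int]:
    path = Path(path)
    raw = pd.read_csv(path)
    missing = [c for c in colmap if c not in raw.columns]
    if missing:
        raise DialectError(f"{path.name}: missing column(s) {missing}")
    df = raw[list(colmap)].rename(columns=colmap)
    coerced = df.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna().any(axis=1)
    skipped = int(bad.sum())
    if skipped:
        log.warning("%s: skipped %d malformed row(s)", path.name, skipped)
    out = coerced.loc[~bad].sort_values(sort_col, kind="mergesort").reset_index(drop=True)
    return out, skipped


def read_pupil_exports(directory, dialect: GazeExportDialect | None = None):
    """Read ``gaze_positions.csv`` and ``fixations.csv`` from a level dir.

    Returns (gaze, fixations, skip_counts): typed, time-sorted frames with
    canonical column names; malformed rows are counted and skipped.
    Missing files yield empty frames.
    """
    dialect = dialect or GazeExportDialect()
    directory = Path(directory)
    skips = {}
    gpath = directory / "gaze_positions.csv"
    fpath = directory / "fixations.csv"
    if gpath.exists() and gpath.stat().st_size > 0:
        gaze, skips["gaze"] = _read_export(gpath, dialect.gaze_map(), "t")
    else:
        gaze, skips["gaze"] = pd.DataFrame(columns=GAZE_COLUMNS), 0
    if fpath.exists() and fpath.stat().st_size > 0:
        fix, skips["fixations"] = _read_export(fpath, dialect.fixation_map(), "t_start")
    else:
        fix, skips["fixations"] = pd.DataFrame(columns=FIXATION_COLUMNS), 0
    return gaze, fix, skips


def write_gaze_exports(gaze: pd.DataFrame, fixations: pd.DataFrame, directory, dialect=None) -> None:
    dialect = dialect or GazeExportDialect()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    inv_g = {v: k for k, v in dialect.gaze_map().items()}
    inv_f = {v: k for k, v in dialect.fixation_map().items()}
    gaze.rename(columns=inv_g).to_csv(directory / "gaze_positions.csv", index=False)
    fixations.rename(columns=inv_f).to_csv(directory / "fixations.csv", index=False)


def read_cohort(cohort_dir, dialect: GazeExportDialect | None = None):
    """Read a cohort directory written by ``synthetic.write_cohort`` back
    into SubjectRecord objects (latent abilities come from the manifest and
    are NaN when absent)."""
    from .scoring import BVSCOResult, NormativeTable
    from .synthetic import SimulatedGaze, SubjectRecord

    dialect = dialect or GazeExportDialect()
    cohort_dir = Path(cohort_dir)
    norms = NormativeTable.from_csv(cohort_dir / "norms.csv")
    manifest = json.loads((cohort_dir / "manifest.json").read_text())
    abilities = manifest.get("latent_ability", {})
    records = []
    for sdir in sorted(p for p in cohort_dir.iterdir() if p.is_dir()):
        sid = sdir.name
        game_log = json.loads((sdir / "game_log.json").read_text())
        quest = json.loads((sdir / "questionnaire.json").read_text())
        bv = pd.read_csv(sdir / "bvsco.csv").iloc[0]
        gaze = {}
        levels_dir = sdir / "levels"
        if levels_dir.exists():
            for ldir in sorted(levels_dir.iterdir()):
                g, f, _ = read_pupil_exports(ldir, dialect)
                gaze[ldir.name] = SimulatedGaze(samples=g, fixations=f)
        drawings = {}
        for spath in sorted(sdir.glob("strokes_*.csv")):
            level = spath.stem.replace("strokes_", "")
            drawings[level] = pd.read_csv(spath)
        records.append(
            SubjectRecord(
                subject_id=sid,
                grade=int(bv["grade"]),
                sex=str(quest.get("sex", "")),
                ability=float(abilities.get(sid, float("nan"))),
                game_log=game_log,
                gaze=gaze,
                drawings=drawings,
                bvsco=BVSCOResult(int(bv["grade"]), (int(bv["c1"]), int(bv["c2"]), int(bv["c3"]))),
                sus_responses=quest.get("sus_responses", []),
                questionnaire=quest,
            )
        )
    return records, norms
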