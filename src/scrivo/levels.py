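"""Catalog of the serious game's levels and screen layouts.

The battery contains six visual-perception games, each played at three
difficulties.  Four games present a reference image in a left panel and
three candidate answers stacked in the right half of the screen
("options" games); figure-ground search uses the whole screen as a single
panel; copying and tracing are drawing games.

Screen coordinates are normalized to [0, 1] x [0, 1] with the origin at
the bottom-left corner (the eye-tracker export convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DIFFICULTIES = ("easy", "medium", "hard")

#: game id -> kind ("options": target + 3 answer panels, "search": one panel,
#: "copy"/"trace": drawing games)
GAMES = {
    "form_constancy": "options",
    "masked_form_constancy": "options",
    "visual_closure": "options",
    "figure_ground": "search",
    "copying": "copy",
    "tracing": "trace",
}

ROLE_TARGET = "TARGET"
ROLE_CORRECT = "OPTION_CORRECT"
ROLE_WRONG = "OPTION_WRONG"

PANEL_POSITIONS = ("left", "right_top", "right_middle", "right_bottom")

#: canonical panel centers for the four-panel screens
PANEL_CENTERS = {
    "left": (0.25, 0.5),
    "right_top": (0.75, 0.83),
    "right_middle": (0.75, 0.5),
    "right_bottom": (0.75, 0.17),
}


class LayoutError(ValueError):
    """Raised when a level layout violates its panel contract."""


@dataclass(frozen=True)
class LevelLayout:
    """Semantic panel layout of a level.

    ``role_by_position`` maps a panel position to its task role; four-panel
    layouts must contain exactly one TARGET and one OPTION_CORRECT.
    """

    level_id: str
    n_panels: int
    role_by_position: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_panels == 4:
            roles = list(self.role_by_position.values())
            if roles.count(ROLE_TARGET) != 1:
                raise LayoutError(f"{self.level_id}: need exactly one TARGET panel")
            if roles.count(ROLE_CORRECT) != 1:
                raise LayoutError(f"{self.level_id}: need exactly one OPTION_CORRECT panel")
        elif self.n_panels != 1:
            raise LayoutError(f"{self.level_id}: n_panels must be 1 or 4")


def level_id(game: str, difficulty: str) -> str:
    return f"{game}_{difficulty}"


def options_layout(level: str, correct_position: str = "right_middle") -> LevelLayout:
    """Four-panel layout: target on the left, one correct option at
    ``correct_position`` among the three right panels."""
    roles = {"left": ROLE_TARGET}
    for pos in ("right_top", "right_middle", "right_bottom"):
        roles[pos] = ROLE_CORRECT if pos == correct_position else ROLE_WRONG
    return LevelLayout(level, 4, roles)


def search_layout(level: str) -> LevelLayout:
    return LevelLayout(level, 1, {"full": ROLE_TARGET})


# the correct option rotates with difficulty so that layouts differ
_CORRECT_BY_DIFFICULTY = {"easy": "right_top", "medium": "right_middle", "hard": "right_bottom"}


def default_layouts() -> dict:
    """All gaze-relevant level layouts of the battery."""
    layouts = {}
    for game, kind in GAMES.items():
        for diff in DIFFICULTIES:
            lid = level_id(game, diff)
            if kind == "options":
                layouts[lid] = options_layout(lid, _CORRECT_BY_DIFFICULTY[diff])
            elif kind == "search":
                layouts[lid] = search_layout(lid)
    return layouts


def gaze_levels() -> list:
    """Levels for which gaze streams are recorded (non-drawing games)."""
    return [
        level_id(g, d)
        for g, kind in GAMES.items()
        if kind in ("options", "search")
        for d in DIFFICULTIES
    ]


def drawing_levels() -> list:
    return [
        level_id(g, d)
        for g, kind in GAMES.items()
        if kind in ("copy", "trace")
        for d in DIFFICULTIES
    ]


def all_levels() -> list:
    return [level_id(g, d) for g in GAMES for d in DIFFICULTIES]


# ---------------------------------------------------------------------------
# drawing templates
# ---------------------------------------------------------------------------

def _square(cx: float, cy: float, half: float) -> np.ndarray:
    return np.array(
        [
            [cx - half, cy - half],
            [cx + half, cy - half],
            [cx + half, cy + half],
            [cx - half, cy + half],
            [cx - half, cy - half],
        ]
    )


def _zigzag(cx: float, cy: float, half: float) -> np.ndarray:
    xs = np.linspace(cx - half, cx + half, 7)
    ys = np.where(np.arange(7) % 2 == 0, cy - half * 0.8, cy + half * 0.8)
    return np.column_stack([xs, ys])


def _star(cx: float, cy: float, r: float) -> np.ndarray:
    ang = np.pi / 2 + np.arange(11) * (4 * np.pi / 5) / 2.0
    rad = np.where(np.arange(11) % 2 == 0, r, 0.45 * r)
    return np.column_stack([cx + rad * np.cos(ang), cy + rad * np.sin(ang)])


def drawing_template(level: str) -> list:
    """Reference polylines for a drawing level.

    Returns a list of strokes; each stroke is an (n, 2) array of normalized
    coordinates.  Copying levels place the drawing canvas in the right half
    of the screen, tracing levels in the center.
    """
    game = "copying" if level.startswith("copying") else "tracing"
    diff = level.rsplit("_", 1)[1]
    cx, cy = (0.68, 0.5) if game == "copying" else (0.5, 0.5)
    if diff == "easy":
        return [_square(cx, cy, 0.12)]
    if diff == "medium":
        # house: square body plus a separate triangular roof stroke
        body = _square(cx, cy - 0.03, 0.11)
        roof = np.array([[cx - 0.11, cy + 0.08], [cx, cy + 0.19], [cx + 0.11, cy + 0.08]])
        return [body, roof]
    return [_star(cx, cy, 0.15), _zigzag(cx, cy - 0.22, 0.1)]
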