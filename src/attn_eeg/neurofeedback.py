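"""Headless closed-loop game control driven by quantized attention levels.

The five ordinal attention levels map onto control values
{0, 0.25, 0.5, 0.75, 1}.  Three game rules consume one control value per
tick (one classifier prediction):

sustained  the character advances only while the control value exceeds a
           threshold; the session is won once advances outnumber retreats
           by a configured margin (win_time = ticks to first win).
selective  the control value steers a bird upward / horizontal / downward
           over a deterministic obstacle course; the score is the number of
           ticks survived.
focus      a special skill fires on every tick at the maximum level; the
           firing ticks are recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .eeg_io import AttentionLevel

__all__ = [
    "CONTROL_VALUES",
    "GameConfig",
    "SessionLog",
    "quantize",
    "sustained_step",
    "selective_step",
    "focus_step",
    "run_session",
]

CONTROL_VALUES = (0.0, 0.25, 0.5, 0.75, 1.0)

#: flight directions ordered low to high altitude
DIRECTIONS = ("downward", "horizontal", "upward")


@dataclass(frozen=True)
class GameConfig:
    """Knobs of the three game rules.

    ``course`` lists, per tick, the minimum direction the bird must hold to
    avoid the obstacle ("downward" poses no constraint); it is cycled when
    shorter than the session.
    """

    sustained_threshold: float = 0.5
    win_margin: int = 10
    course: tuple[str, ...] = (
        "downward", "downward", "horizontal", "downward", "upward",
        "downward", "horizontal", "horizontal", "downward", "upward",
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.sustained_threshold < 1.0:
            raise ValueError("sustained threshold must lie in (0, 1)")
        if self.win_margin < 1:
            raise ValueError("win margin must be >= 1")
        bad = [d for d in self.course if d not in DIRECTIONS]
        if bad:
            raise ValueError(f"unknown direction(s) in course: {bad}")


@dataclass
class SessionLog:
    """Tick-aligned record of one game session plus its training indicators."""

    game: str
    levels: list[AttentionLevel]
    control: list[float]
    events: list[str]
    win_time: int | None = None
    game_score: int | None = None
    skill_times: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not len(self.levels) == len(self.control) == len(self.events):
            raise ValueError("levels, control and events must be tick-aligned")

    def to_dict(self) -> dict:
        return {
            "game": self.game,
            "levels": [int(l) for l in self.levels],
            "control": self.control,
            "events": self.events,
            "win_time": self.win_time,
            "game_score": self.game_score,
            "skill_times": self.skill_times,
        }


def quantize(level: AttentionLevel) -> float:
    """low->0, medium-low->0.25, medium->0.5, medium-high->0.75, high->1."""
    level = AttentionLevel.from_any(level)
    return CONTROL_VALUES[int(level)]


def sustained_step(c: float, threshold: float = 0.5) -> str:
    """'advance' iff the control value strictly exceeds the threshold."""
    return "advance" if c > threshold else "retreat"


def selective_step(c: float) -> str:
    """c >= 0.75 -> upward; c == 0.5 -> horizontal; c <= 0.25 -> downward."""
    if c >= 0.75:
        return "upward"
    if c >= 0.5:
        return "horizontal"
    return "downward"


def focus_step(c: float) -> str:
    """'release' only at the maximum attention level (c == 1)."""
    return "release" if c >= 1.0 else "idle"


def run_session(
    level_stream: Sequence[AttentionLevel],
    game: str,
    game_config: GameConfig | None = None,
) -> SessionLog:
    """Quantize a level stream and run it through one game rule tick by tick."""
    if len(level_stream) == 0:
        raise ValueError("level stream must be non-empty")
    if game not in ("sustained", "selective", "focus"):
        raise ValueError(f"unknown game {game!r}; expected sustained|selective|focus")
    cfg = game_config or GameConfig()
    levels = [AttentionLevel.from_any(l) for l in level_stream]
    control = [quantize(l) for l in levels]
    log = SessionLog(game=game, levels=levels, control=control,
                     events=["" for _ in levels])

    if game == "sustained":
        position = 0
        for t, c in enumerate(control):
            ev = sustained_step(c, cfg.sustained_threshold)
            log.events[t] = ev
            position += 1 if ev == "advance" else -1
            if log.win_time is None and position >= cfg.win_margin:
                log.win_time = t + 1  # ticks elapsed at the moment of winning
    elif game == "selective":
        crashed_at = None
        for t, c in enumerate(control):
            direction = selective_step(c)
            floor = cfg.course[t % len(cfg.course)]
            if DIRECTIONS.index(direction) < DIRECTIONS.index(floor):
                log.events[t] = "collision"
                crashed_at = t
                break
            log.events[t] = direction
        if crashed_at is not None:
            # session ends on collision; truncate to the played ticks
            end = crashed_at + 1
            log.levels = log.levels[:end]
            log.control = log.control[:end]
            log.events = log.events[:end]
            log.game_score = crashed_at
        else:
            log.game_score = len(control)
    else:  # focus
        for t, c in enumerate(control):
            ev = focus_step(c)
            log.events[t] = ev
            if ev == "release":
                log.skill_times.append(t)
    return log
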