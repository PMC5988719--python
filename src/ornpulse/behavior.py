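"""Choice-assay trajectory analysis.

Larvae move on a circular plate split into four quadrants by two
perpendicular lines through the center; one diagonal pair of quadrants
is illuminated. This module assigns positions to quadrants, computes
the performance index (PI), detects discrete boundary-approach events
with a hysteresis band, and turns them into entry / turn-back
probabilities with the raw counts needed for Fisher testing.

PI convention: PI = (positions in lit quadrants - positions in dark
quadrants) / (classified positions), pooled over larvae and frames.
Positions inside the exclusion band around the boundary lines are
excluded from all counts, which keeps PI in [-1, 1] and avoids
tie-breaking artifacts. A literal per-larva denominator variant is
available behind ``denominator='larvae'``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ArenaConfig",
    "TrajectorySet",
    "BoundaryEvent",
    "PerformanceIndexResult",
    "BoundaryProbabilities",
    "assign_quadrant",
    "performance_index",
    "detect_boundary_events",
    "boundary_probabilities",
    "events_to_table",
    "approach_count_table",
]

WALL_TOL = 1e-6  # cm; tolerance for "inside the arena" checks


@dataclass
class ArenaConfig:
    """Circular four-quadrant arena; one diagonal quadrant pair is lit.

    ``lit_pair`` is "I-III" (quadrants where the rotated coordinates
    have equal signs) or "II-IV".
    """

    radius: float = 5.0
    center: tuple[float, float] = (0.0, 0.0)
    quadrant_axes_angle: float = 0.0  # degrees
    lit_pair: str = "I-III"

    def __post_init__(self) -> None:
        if not (self.radius > 0):
            raise ValueError("radius must be > 0")
        if self.lit_pair not in ("I-III", "II-IV"):
            raise ValueError("lit_pair must be 'I-III' or 'II-IV'")

    def to_rotated(self, xy: np.ndarray) -> np.ndarray:
        """Map world coordinates to the quadrant frame (boundary lines = axes)."""
        xy = np.asarray(xy, dtype=float)
        p = xy - np.asarray(self.center)
        a = -math.radians(self.quadrant_axes_angle)
        R = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
        return p @ R.T

    def from_rotated(self, uv: np.ndarray) -> np.ndarray:
        uv = np.asarray(uv, dtype=float)
        a = math.radians(self.quadrant_axes_angle)
        R = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
        return uv @ R.T + np.asarray(self.center)

    def quadrant_is_lit(self, quadrant: int) -> bool:
        if self.lit_pair == "I-III":
            return quadrant in (1, 3)
        return quadrant in (2, 4)

    def swapped(self) -> "ArenaConfig":
        other = "II-IV" if self.lit_pair == "I-III" else "I-III"
        return ArenaConfig(self.radius, self.center, self.quadrant_axes_angle, other)


@dataclass
class TrajectorySet:
    """Per-larva ordered positions; ``positions[id]`` is a (T, 2) array in cm."""

    positions: dict[int, np.ndarray]
    frame_rate: float = 1.0

    def __post_init__(self) -> None:
        if not self.positions:
            raise ValueError("trajectory set is empty")
        if not (self.frame_rate > 0):
            raise ValueError("frame_rate must be > 0")
        self.positions = {
            k: np.asarray(v, dtype=float) for k, v in self.positions.items()
        }
        for k, v in self.positions.items():
            if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 1:
                raise ValueError(f"larva {k}: positions must be a (T, 2) array")

    @property
    def n_larvae(self) -> int:
        return len(self.positions)

    @property
    def n_positions(self) -> int:
        return sum(v.shape[0] for v in self.positions.values())

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for larva_id in sorted(self.positions):
            pos = self.positions[larva_id]
            for frame, (x, y) in enumerate(pos):
                rows.append((larva_id, frame, x, y))
        return pd.DataFrame(rows, columns=["larva_id", "frame", "x_cm", "y_cm"])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, frame_rate: float = 1.0) -> "TrajectorySet":
        required = {"larva_id", "frame", "x_cm", "y_cm"}
        if not required.issubset(df.columns):
            raise ValueError(f"trajectory table must have columns {sorted(required)}")
        positions = {}
        for larva_id, grp in df.groupby("larva_id"):
            grp = grp.sort_values("frame")
            frames = grp["frame"].to_numpy()
            if np.any(np.diff(frames) <= 0):
                raise ValueError(f"larva {larva_id}: frames not strictly increasing")
            positions[int(larva_id)] = grp[["x_cm", "y_cm"]].to_numpy(dtype=float)
        return cls(positions, frame_rate)

    def write(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def read(cls, path, frame_rate: float = 1.0) -> "TrajectorySet":
        return cls.from_dataframe(pd.read_csv(path, sep="\t"), frame_rate)


@dataclass
class BoundaryEvent:
    larva_id: int
    time: float  # s, at band entry
    origin_side: str  # 'lit' | 'dark'
    outcome: str  # 'cross' | 'turn_back'

    def __post_init__(self) -> None:
        if self.origin_side not in ("lit", "dark"):
            raise ValueError("origin_side must be 'lit' or 'dark'")
        if self.outcome not in ("cross", "turn_back"):
            raise ValueError("outcome must be 'cross' or 'turn_back'")


@dataclass
class PerformanceIndexResult:
    pi: float
    n_light: int
    n_dark: int
    n_total: int
    n_larvae: int


@dataclass
class BoundaryProbabilities:
    p_enter_lit: float | None
    n_dark_approaches: int
    p_turn_back: float | None
    n_lit_approaches: int
    crosses_from_dark: int = 0
    turn_backs_from_lit: int = 0


def assign_quadrant(position, arena: ArenaConfig) -> tuple[int | None, bool | None]:
    """Quadrant id (1-4) and lit flag; (None, None) exactly on a boundary line.

    Positions outside the arena circle (beyond a small wall tolerance)
    are rejected.
    """
    u, v = arena.to_rotated(np.asarray(position, dtype=float))
    if math.hypot(u, v) > arena.radius + WALL_TOL:
        raise ValueError(f"position {tuple(position)} lies outside the arena")
    if u == 0.0 or v == 0.0:
        return None, None
    if u > 0:
        q = 1 if v > 0 else 4
    else:
        q = 2 if v > 0 else 3
    return q, arena.quadrant_is_lit(q)


def _classify_positions(uv: np.ndarray, arena: ArenaConfig, band_width: float):
    """Vectorized lit/dark/band classification in rotated coordinates."""
    u, v = uv[:, 0], uv[:, 1]
    band = np.minimum(np.abs(u), np.abs(v)) <= band_width
    same_sign = (u > 0) == (v > 0)
    lit = same_sign if arena.lit_pair == "I-III" else ~same_sign
    return lit, band


def performance_index(
    trajectories: TrajectorySet,
    arena: ArenaConfig,
    band_width: float = 0.0,
    denominator: str = "positions",
) -> PerformanceIndexResult:
    """Performance index over all larvae and frames.

    PI = (n_light - n_dark) / n_total with n_total the classified
    positions (band positions excluded from every count). The literal
    per-larva denominator divides the count difference by the number of
    larvae instead (``denominator='larvae'``; not bounded by [-1, 1]).
    """
    n_light = n_dark = 0
    for larva_id, pos in trajectories.positions.items():
        uv = arena.to_rotated(pos)
        r = np.hypot(uv[:, 0], uv[:, 1])
        if np.any(r > arena.radius + WALL_TOL):
            raise ValueError(f"larva {larva_id} has positions outside the arena")
        lit, band = _classify_positions(uv, arena, band_width)
        n_light += int(np.sum(lit & ~band))
        n_dark += int(np.sum(~lit & ~band))
    n_total = n_light + n_dark
    if n_total == 0:
        raise ValueError("no classifiable positions (all in the boundary band)")
    if denominator == "positions":
        pi = (n_light - n_dark) / n_total
    elif denominator == "larvae":
        pi = (n_light - n_dark) / trajectories.n_larvae
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return PerformanceIndexResult(pi, n_light, n_dark, n_total, trajectories.n_larvae)


def detect_boundary_events(
    trajectories: TrajectorySet,
    arena: ArenaConfig,
    band_width: float = 0.5,
    max_dwell: float = 10.0,
) -> list[BoundaryEvent]:
    """Detect discrete boundary-approach events with a hysteresis band.

    An event opens when a larva whose last definite side was S enters
    the band (distance to the nearest quadrant-boundary line <
    ``band_width``). It closes as 'cross' as soon as the larva's
    quadrant lit-flag differs from S (inside or outside the band), as
    'turn_back' when it exits the band still on side S, and as
    'turn_back' if it dwells in the band longer than ``max_dwell``
    seconds without the flag flipping. One outcome per band visit; a
    new event requires leaving the band first.
    """
    if not (band_width > 0):
        raise ValueError("band_width must be > 0")
    if band_width >= arena.radius:
        raise ValueError("band_width must be smaller than the arena radius")
    events: list[BoundaryEvent] = []
    for larva_id in sorted(trajectories.positions):
        pos = trajectories.positions[larva_id]
        uv = arena.to_rotated(pos)
        lit, band = _classify_positions(uv, arena, band_width)
        last_side: bool | None = None  # lit flag of last out-of-band frame
        open_event: tuple[float, bool] | None = None  # (entry time, origin lit)
        for i in range(pos.shape[0]):
            t = i / trajectories.frame_rate
            if open_event is not None:
                t0, origin_lit = open_event
                origin = "lit" if origin_lit else "dark"
                if lit[i] != origin_lit:
                    events.append(BoundaryEvent(larva_id, t0, origin, "cross"))
                    open_event = None
                elif not band[i]:
                    events.append(BoundaryEvent(larva_id, t0, origin, "turn_back"))
                    open_event = None
                elif t - t0 > max_dwell:
                    events.append(BoundaryEvent(larva_id, t0, origin, "turn_back"))
                    open_event = None
                if open_event is None and band[i]:
                    last_side = None  # require a clean band exit before a new event
            elif band[i]:
                if last_side is not None:
                    open_event = (t, last_side)
            if not band[i]:
                last_side = bool(lit[i])
        # an event still open at the end of the recording has no outcome; drop it
    return events


def boundary_probabilities(events: list[BoundaryEvent]) -> BoundaryProbabilities:
    """Entry and turn-back probabilities from boundary events.

    p_enter_lit = crosses from dark / approaches from dark;
    p_turn_back = turn-backs from lit / approaches from lit.
    A side with zero approaches yields None with a warning.
    """
    dark = [e for e in events if e.origin_side == "dark"]
    litd = [e for e in events if e.origin_side == "lit"]
    crosses_from_dark = sum(1 for e in dark if e.outcome == "cross")
    turn_backs_from_lit = sum(1 for e in litd if e.outcome == "turn_back")
    p_enter = crosses_from_dark / len(dark) if dark else None
    p_turn = turn_backs_from_lit / len(litd) if litd else None
    if p_enter is None:
        warnings.warn("no approaches from the dark side; entry probability undefined", stacklevel=2)
    if p_turn is None:
        warnings.warn("no approaches from the lit side; turn-back probability undefined", stacklevel=2)
    return BoundaryProbabilities(
        p_enter, len(dark), p_turn, len(litd), crosses_from_dark, turn_backs_from_lit
    )


def events_to_table(events: list[BoundaryEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.larva_id, e.time, e.origin_side, e.outcome) for e in events],
        columns=["larva_id", "time_s", "origin", "outcome"],
    )


def approach_count_table(
    probs_a: BoundaryProbabilities, probs_b: BoundaryProbabilities, side: str = "lit"
) -> np.ndarray:
    """2x2 counts (group x outcome) for Fisher testing of boundary behavior."""
    if side == "lit":
        return np.array(
            [
                [probs_a.turn_backs_from_lit, probs_a.n_lit_approaches - probs_a.turn_backs_from_lit],
                [probs_b.turn_backs_from_lit, probs_b.n_lit_approaches - probs_b.turn_backs_from_lit],
            ]
        )
    if side == "dark":
        return np.array(
            [
                [probs_a.crosses_from_dark, probs_a.n_dark_approaches - probs_a.crosses_from_dark],
                [probs_b.crosses_from_dark, probs_b.n_dark_approaches - probs_b.crosses_from_dark],
            ]
        )
    raise ValueError("side must be 'lit' or 'dark'")
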