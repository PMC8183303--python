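"""Stimulus grid and change-event scheduling.

One experiment video shows 150 small objects (40 x 40 px squares or
triangles, red or green, rotated 0 or 45 degrees) arranged in a 25 x 6 grid
with 200 px center-to-center spacing across the unrolled three-canvas plane.
During a 5-minute video, 140 events of each change type (color, shape,
motion) are scheduled: each event is visible for 1-2 s, events of the same
type never overlap, and the pause between consecutive same-type events is at
most 1 s.  Colors are defined in LAB space and color changes move a single
chromatic channel so luminosity stays constant; motion events wiggle the
object around 45 degrees.

Occluded grid cells (hidden behind the vehicle chassis) never receive
events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureObject",
    "FeatureGrid",
    "ChangeEvent",
    "StimulusState",
    "SchedulingError",
    "CHANGE_TYPES",
    "GRID_COLS",
    "GRID_ROWS",
    "GRID_SPACING_PX",
    "OBJECT_SIZE_PX",
    "LAB_RED",
    "LAB_GREEN",
    "default_occlusion_mask",
    "generate_grid",
    "schedule_events",
    "validate_schedule",
    "state_at",
    "events_to_frame",
    "events_from_frame",
]

CHANGE_TYPES = ("color", "shape", "motion")

GRID_COLS = 25
GRID_ROWS = 6
GRID_SPACING_PX = 200
OBJECT_SIZE_PX = 40

#: LAB coordinates of the two object colors.  Only the a (green-red) channel
#: differs, so interpolating a alone keeps lightness L constant.
LAB_RED = (60.0, 60.0, 45.0)
LAB_GREEN = (60.0, -60.0, 45.0)

#: Default wiggle frequency for motion events (Hz); at least two full
#: oscillations fit into the 1 s minimum event duration.
DEFAULT_WIGGLE_HZ = 2.0


class SchedulingError(RuntimeError):
    """Raised when an event schedule cannot satisfy its constraints."""


@dataclass(frozen=True)
class FeatureObject:
    feature_id: int
    screen_id: int
    x: float  # pixel coordinates of the object center (per-screen)
    y: float
    col: int  # grid cell
    row: int
    shape: str  # "square" | "triangle"
    color: str  # "red" | "green"
    orientation_deg: float  # 0 or 45
    visible: bool


@dataclass
class ChangeEvent:
    event_id: int
    change_type: str
    feature_id: int
    onset: float
    offset: float

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class StimulusState:
    """Instantaneous per-feature state at some time t.

    Arrays are indexed by feature_id (length = number of grid objects).
    """

    t: float
    lab: np.ndarray  # (n, 3) LAB color
    morph: np.ndarray  # (n,) shape-morph parameter in [0, 1]
    wiggle_deg: np.ndarray  # (n,) wiggle angle around the base orientation


@dataclass
class FeatureGrid:
    """The 25 x 6 arrangement of stimulus objects on the unrolled canvas."""

    features: list[FeatureObject]
    occlusion: np.ndarray  # (rows, cols) bool, True = visible
    seed: int
    columns_px: int = 1920  # per-screen pixel columns, for unrolling

    def __post_init__(self) -> None:
        self.occlusion = np.asarray(self.occlusion, dtype=bool)

    def __len__(self) -> int:
        return len(self.features)

    @property
    def visible_ids(self) -> np.ndarray:
        return np.array([f.feature_id for f in self.features if f.visible], dtype=int)

    def feature(self, feature_id: int) -> FeatureObject:
        return self.features[feature_id]

    def positions_unrolled(self, only_visible: bool = False) -> np.ndarray:
        """(n, 2) array of object centers on the unrolled pixel plane."""
        feats = [f for f in self.features if f.visible or not only_visible]
        return np.array(
            [[f.screen_id * self.columns_px + f.x, f.y] for f in feats], dtype=float
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": [f.feature_id for f in self.features],
                "screen_id": [f.screen_id for f in self.features],
                "x": [f.x for f in self.features],
                "y": [f.y for f in self.features],
                "col": [f.col for f in self.features],
                "row": [f.row for f in self.features],
                "shape": [f.shape for f in self.features],
                "color": [f.color for f in self.features],
                "orientation_deg": [f.orientation_deg for f in self.features],
                "visible": [f.visible for f in self.features],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, occlusion: np.ndarray | None = None, seed: int = -1) -> "FeatureGrid":
        feats = [
            FeatureObject(
                feature_id=int(r.feature_id),
                screen_id=int(r.screen_id),
                x=float(r.x),
                y=float(r.y),
                col=int(r.col),
                row=int(r.row),
                shape=str(r.shape),
                color=str(r.color),
                orientation_deg=float(r.orientation_deg),
                visible=bool(r.visible),
            )
            for r in df.itertuples()
        ]
        if occlusion is None:
            occlusion = np.ones((GRID_ROWS, GRID_COLS), dtype=bool)
            for f in feats:
                occlusion[f.row, f.col] = f.visible
        return cls(features=feats, occlusion=occlusion, seed=seed)


def _grid_positions(columns_px: int = 1920, rows_px: int = 1200):
    """Global-x / y pixel centers of the 25 x 6 grid, centered on the canvas."""
    total_w = 3 * columns_px
    x0 = (total_w - (GRID_COLS - 1) * GRID_SPACING_PX) / 2.0
    y0 = (rows_px - (GRID_ROWS - 1) * GRID_SPACING_PX) / 2.0
    xs = x0 + GRID_SPACING_PX * np.arange(GRID_COLS)
    ys = y0 + GRID_SPACING_PX * np.arange(GRID_ROWS)
    return xs, ys


def default_occlusion_mask() -> np.ndarray:
    """Default chassis occlusion: the bottom two grid rows of the center
    screen are hidden behind the vehicle.  (rows, cols) bool, True = visible."""
    mask = np.ones((GRID_ROWS, GRID_COLS), dtype=bool)
    xs, _ = _grid_positions()
    center_cols = np.where((xs >= 1920) & (xs < 3840))[0]
    mask[np.ix_([GRID_ROWS - 2, GRID_ROWS - 1], center_cols)] = False
    return mask


def generate_grid(
    seed: int,
    occlusion: np.ndarray | None = None,
    columns_px: int = 1920,
    rows_px: int = 1200,
) -> FeatureGrid:
    """Generate the randomized 25 x 6 feature grid.

    Shape, color and orientation are independent uniform draws per object;
    visibility comes from the occlusion mask.  Deterministic given ``seed``.
    """
    if occlusion is None:
        occlusion = np.ones((GRID_ROWS, GRID_COLS), dtype=bool)
    occlusion = np.asarray(occlusion, dtype=bool)
    if occlusion.shape != (GRID_ROWS, GRID_COLS):
        raise ValueError(
            f"occlusion mask must be {(GRID_ROWS, GRID_COLS)}, got {occlusion.shape}"
        )
    rng = np.random.default_rng(seed)
    xs, ys = _grid_positions(columns_px, rows_px)
    features: list[FeatureObject] = []
    fid = 0
    shapes = rng.choice(["square", "triangle"], size=GRID_ROWS * GRID_COLS)
    colors = rng.choice(["red", "green"], size=GRID_ROWS * GRID_COLS)
    orients = rng.choice([0.0, 45.0], size=GRID_ROWS * GRID_COLS)
    for row in range(GRID_ROWS):
        for col in range(GRID_COLS):
            gx = xs[col]
            screen_id = int(gx // columns_px)
            features.append(
                FeatureObject(
                    feature_id=fid,
                    screen_id=screen_id,
                    x=float(gx - screen_id * columns_px),
                    y=float(ys[row]),
                    col=col,
                    row=row,
                    shape=str(shapes[fid]),
                    color=str(colors[fid]),
                    orientation_deg=float(orients[fid]),
                    visible=bool(occlusion[row, col]),
                )
            )
            fid += 1
    return FeatureGrid(features=features, occlusion=occlusion, seed=seed, columns_px=columns_px)


# ---------------------------------------------------------------------------
# event scheduling


def _schedule_one_type(
    rng: np.random.Generator,
    video_length: float,
    count: int,
    min_dur: float,
    max_dur: float,
    max_gap: float,
    max_tries: int = 1000,
) -> list[tuple[float, float]]:
    """Sample (onset, offset) pairs for one change type by rejection.

    Durations are uniform in [min_dur, max_dur]; gaps between consecutive
    events (and before the first event) are uniform in (0, max_gap].  A draw
    that overruns the video is rejected and resampled wholesale.
    """
    for _ in range(max_tries):
        durations = rng.uniform(min_dur, max_dur, size=count)
        gaps = max_gap * (1.0 - rng.random(size=count))  # uniform in (0, max_gap]
        onsets = np.cumsum(gaps) + np.concatenate([[0.0], np.cumsum(durations[:-1])])
        offsets = onsets + durations
        if offsets[-1] <= video_length:
            return list(zip(onsets.tolist(), offsets.tolist()))
    raise SchedulingError(
        f"could not fit {count} events of {min_dur}-{max_dur} s into {video_length} s"
    )


def schedule_events(
    grid: FeatureGrid,
    video_length: float = 300.0,
    per_type_count: int = 140,
    seed: int = 0,
    min_duration: float = 1.0,
    max_duration: float = 2.0,
    max_gap: float = 1.0,
) -> list[ChangeEvent]:
    """Schedule change events for one video.

    Exactly ``per_type_count`` events of each of the three change types are
    placed.  Same-type events never overlap and are separated by at most
    ``max_gap`` seconds; different types may overlap in time but never target
    the same feature simultaneously.  Target features are drawn uniformly
    from the visible features.
    """
    if per_type_count < 0:
        raise ValueError("per_type_count must be >= 0")
    if per_type_count == 0:
        return []
    if per_type_count * min_duration > video_length:
        raise SchedulingError(
            f"{per_type_count} events of >= {min_duration} s cannot fit in {video_length} s"
        )
    visible = grid.visible_ids
    if len(visible) == 0:
        raise SchedulingError("no visible features to schedule events on")

    rng = np.random.default_rng(seed)
    timed: list[tuple[float, float, str]] = []
    for ctype in CHANGE_TYPES:
        for onset, offset in _schedule_one_type(
            rng, video_length, per_type_count, min_duration, max_duration, max_gap
        ):
            timed.append((onset, offset, ctype))
    timed.sort(key=lambda e: e[0])

    # assign features: uniform over visible features not currently engaged in
    # a temporally overlapping event of any type
    events: list[ChangeEvent] = []
    active: list[tuple[float, int]] = []  # (offset, feature_id)
    for i, (onset, offset, ctype) in enumerate(timed):
        active = [(off, f) for off, f in active if off > onset]
        busy = {f for _, f in active}
        candidates = np.array([f for f in visible if f not in busy], dtype=int)
        if len(candidates) == 0:
            raise SchedulingError("all visible features busy; grid too small for schedule")
        fid = int(rng.choice(candidates))
        active.append((offset, fid))
        events.append(ChangeEvent(i, ctype, fid, float(onset), float(offset)))
    return events


def validate_schedule(
    events: list[ChangeEvent],
    grid: FeatureGrid,
    video_length: float = 300.0,
    min_duration: float = 1.0,
    max_duration: float = 2.0,
    max_gap: float = 1.0,
    tol: float = 1e-9,
) -> None:
    """Check every schedule invariant; raise ``SchedulingError`` on violation.

    Checks: durations in [min, max]; all events inside the video; same-type
    events non-overlapping with inter-event gaps in (0, max_gap]; no two
    temporally overlapping events on one feature; targets visible.
    """
    visible = set(grid.visible_ids.tolist())
    for ev in events:
        if not (min_duration - tol <= ev.duration <= max_duration + tol):
            raise SchedulingError(f"event {ev.event_id} duration {ev.duration} out of range")
        if ev.onset < -tol or ev.offset > video_length + tol:
            raise SchedulingError(f"event {ev.event_id} outside video")
        if ev.feature_id not in visible:
            raise SchedulingError(f"event {ev.event_id} targets occluded feature")
        if ev.change_type not in CHANGE_TYPES:
            raise SchedulingError(f"event {ev.event_id} has unknown type {ev.change_type}")
    for ctype in CHANGE_TYPES:
        seq = sorted((e for e in events if e.change_type == ctype), key=lambda e: e.onset)
        for prev, nxt in zip(seq, seq[1:]):
            gap = nxt.onset - prev.offset
            if gap <= -tol:
                raise SchedulingError(f"{ctype} events {prev.event_id}/{nxt.event_id} overlap")
            if gap > max_gap + tol:
                raise SchedulingError(
                    f"{ctype} gap {gap:.3f} s between events "
                    f"{prev.event_id}/{nxt.event_id} exceeds {max_gap} s"
                )
    by_onset = sorted(events, key=lambda e: e.onset)
    active: list[ChangeEvent] = []
    for ev in by_onset:
        active = [a for a in active if a.offset > ev.onset + tol]
        if any(a.feature_id == ev.feature_id for a in active):
            raise SchedulingError(f"feature {ev.feature_id} has simultaneous events")
        active.append(ev)


# ---------------------------------------------------------------------------
# instantaneous stimulus state


def state_at(
    grid: FeatureGrid,
    events: list[ChangeEvent],
    t: float,
    wiggle_hz: float = DEFAULT_WIGGLE_HZ,
) -> StimulusState:
    """Per-feature stimulus state at time ``t``.

    Color events interpolate the LAB a channel linearly from the feature's
    base color to its complement over the event; L and b stay constant.
    Shape events drive a morph parameter 0 -> 1; motion events set the wiggle
    angle to ``45 * sin(2 pi f (t - onset))`` degrees.
    """
    n = len(grid)
    lab = np.array(
        [LAB_RED if f.color == "red" else LAB_GREEN for f in grid.features], dtype=float
    )
    morph = np.zeros(n)
    wiggle = np.zeros(n)
    for ev in events:
        if not (ev.onset <= t <= ev.offset):
            continue
        frac = (t - ev.onset) / ev.duration
        fid = ev.feature_id
        if ev.change_type == "color":
            src = LAB_RED if grid.features[fid].color == "red" else LAB_GREEN
            dst = LAB_GREEN if grid.features[fid].color == "red" else LAB_RED
            lab[fid, 1] = src[1] + frac * (dst[1] - src[1])
        elif ev.change_type == "shape":
            morph[fid] = frac
        elif ev.change_type == "motion":
            wiggle[fid] = 45.0 * np.sin(2.0 * np.pi * wiggle_hz * (t - ev.onset))
    return StimulusState(t=float(t), lab=lab, morph=morph, wiggle_deg=wiggle)


# ---------------------------------------------------------------------------
# (de)serialisation


def events_to_frame(events: list[ChangeEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "event_id": [e.event_id for e in events],
            "change_type": [e.change_type for e in events],
            "feature_id": [e.feature_id for e in events],
            "onset_s": [e.onset for e in events],
            "offset_s": [e.offset for e in events],
        }
    )


def events_from_frame(df: pd.DataFrame) -> list[ChangeEvent]:
    return [
        ChangeEvent(
            int(r.event_id), str(r.change_type), int(r.feature_id), float(r.onset_s), float(r.offset_s)
        )
        for r in df.itertuples()
    ]
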