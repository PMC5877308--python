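"""Laboratory observation protocols and their analysis windows.

A lab session is an ordered list of planned activity segments performed
under direct observation. Three protocol parts exercise different aspects
of a posture tracker:

* **Part 1** — six 3-min segments (sitting, standing, four standardized
  walking paces); only the middle minute of each segment is analyzed, the
  first and last minute being transition/recovery. 6 analyzed minutes.
* **Part 2** — five 2-min segments at the participant's own pace. Part 2a
  analyzes the full 10 min including transitions; part 2b excludes the 30 s
  before and after every posture-class change, leaving 10 − k minutes for
  k changes (6–8 min over all orderings; pace changes between two walking
  segments are not posture changes).
* **Part 3** — twelve slow sit-down/get-up cycles (1, 2, 3-s transitions,
  each twice per direction). Each cycle allots 30 s for the posture change;
  the first 30 s of the following hold is analyzed. 6 analyzed minutes.

Windows are half-open [start, end) intervals on the 30-s grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .epochs import ACTIVITIES, EPOCH_SECONDS, ActivityLabel, SecondStream


class LabPart(Enum):
    PART1 = 1
    PART2 = 2
    PART3 = 3


class WindowMode(Enum):
    PART1_MIDDLE = "part1_middle"
    PART2_ALL = "part2_all"
    PART2_EXCL_TRANSITIONS = "part2_excl_transitions"
    PART3_POST_TRANSITION = "part3_post_transition"


#: Margin excluded around a posture change (s) and the maximum time the
#: change itself may take within that margin (s).
TRANSITION_MARGIN = 30
MAX_TRANSITION_SECONDS = 5


class ProtocolMismatchError(ValueError):
    """An operation was applied to the wrong protocol part."""


@dataclass(frozen=True)
class ProtocolSegment:
    """One planned activity period (reference labels only, never IDLE)."""

    activity: ActivityLabel
    planned_duration: int  # seconds
    pace_note: str = ""

    def __post_init__(self) -> None:
        if self.activity not in ACTIVITIES:
            raise ValueError("segment activity must be sitting, standing or walking")
        if self.planned_duration <= 0:
            raise ValueError("planned_duration must be positive")


@dataclass
class LabProtocol:
    """An ordered lab protocol with a UTC start time (UNIX seconds)."""

    part: LabPart
    segments: list[ProtocolSegment]
    start: int = 0

    @property
    def total_seconds(self) -> int:
        return sum(s.planned_duration for s in self.segments)

    def segment_spans(self) -> list[tuple[int, int, ActivityLabel]]:
        """Half-open [start, end) span and activity of every segment."""
        spans = []
        t = self.start
        for seg in self.segments:
            spans.append((t, t + seg.planned_duration, seg.activity))
            t += seg.planned_duration
        return spans


@dataclass
class AnalysisWindowSet:
    """Disjoint, 30-s-aligned half-open analysis intervals."""

    windows: list[tuple[int, int]]
    mode: WindowMode

    def __post_init__(self) -> None:
        prev_end = None
        for lo, hi in self.windows:
            if lo % EPOCH_SECONDS or hi % EPOCH_SECONDS:
                raise ValueError(f"window [{lo}, {hi}) not 30-s aligned")
            if hi <= lo:
                raise ValueError(f"empty or inverted window [{lo}, {hi})")
            if prev_end is not None and lo < prev_end:
                raise ValueError("windows overlap")
            prev_end = hi

    @property
    def total_seconds(self) -> int:
        return sum(hi - lo for lo, hi in self.windows)

    @property
    def total_minutes(self) -> float:
        return self.total_seconds / 60.0

    def contains(self, t: int) -> bool:
        return any(lo <= t < hi for lo, hi in self.windows)

    def epoch_starts(self) -> np.ndarray:
        """Starts of every 30-s epoch fully inside the windows."""
        starts = [
            s
            for lo, hi in self.windows
            for s in range(lo, hi, EPOCH_SECONDS)
        ]
        return np.asarray(starts, dtype=np.int64)


# ---------------------------------------------------------------------------
# Window derivation


def _require_part(p: LabProtocol, part: LabPart) -> None:
    if p.part is not part:
        raise ProtocolMismatchError(f"expected {part.name} protocol, got {p.part.name}")


def windows_part1(p: LabProtocol) -> AnalysisWindowSet:
    """Middle minute of every 3-min part-1 segment.

    The first and last minute of each segment serve as transition/recovery;
    the canonical six-segment protocol yields 6 analyzed minutes.
    """
    _require_part(p, LabPart.PART1)
    windows = [(lo + 60, lo + 120) for lo, hi, _ in p.segment_spans()]
    return AnalysisWindowSet(windows, WindowMode.PART1_MIDDLE)


def posture_class_changes(p: LabProtocol) -> list[int]:
    """Times of posture-class changes between consecutive segments.

    A change exists only where the activity class differs; two adjacent
    walking segments at different paces share class WALKING and do not
    count. No margin applies before the first or after the last segment.
    """
    spans = p.segment_spans()
    return [
        spans[i + 1][0]
        for i in range(len(spans) - 1)
        if spans[i][2] is not spans[i + 1][2]
    ]


def windows_part2(p: LabProtocol, include_transitions: bool) -> AnalysisWindowSet:
    """Part-2 analysis span, with or without transition margins.

    With transitions included the full protocol span is analyzed (10 min for
    the canonical five 2-min segments). Excluding them removes the 30 s
    before and after every posture-class change, i.e. one minute per change;
    overlapping margins from back-to-back changes are merged.
    """
    _require_part(p, LabPart.PART2)
    if not p.segments:
        return AnalysisWindowSet([], WindowMode.PART2_ALL)
    span = (p.start, p.start + p.total_seconds)
    if include_transitions:
        return AnalysisWindowSet([span], WindowMode.PART2_ALL)
    excluded = [
        (t - TRANSITION_MARGIN, t + TRANSITION_MARGIN)
        for t in posture_class_changes(p)
    ]
    windows: list[tuple[int, int]] = []
    cursor = span[0]
    for lo, hi in excluded:  # already sorted; merge as we sweep
        if lo > cursor:
            windows.append((cursor, lo))
        cursor = max(cursor, hi)
    if cursor < span[1]:
        windows.append((cursor, span[1]))
    return AnalysisWindowSet(windows, WindowMode.PART2_EXCL_TRANSITIONS)


def windows_part3(p: LabProtocol) -> AnalysisWindowSet:
    """First 30-s epoch after each part-3 transition allotment.

    Every cycle allots 30 s for the sit-down/get-up; exactly the following
    30 s of the hold is analyzed even if the hold runs long, so the
    canonical twelve cycles yield 6 analyzed minutes.
    """
    _require_part(p, LabPart.PART3)
    windows = [
        (lo + TRANSITION_MARGIN, lo + 2 * TRANSITION_MARGIN)
        for lo, hi, _ in p.segment_spans()
    ]
    return AnalysisWindowSet(windows, WindowMode.PART3_POST_TRANSITION)


def derive_windows(p: LabProtocol, include_transitions: bool = False) -> AnalysisWindowSet:
    """Dispatch to the part-appropriate window rule."""
    if p.part is LabPart.PART1:
        return windows_part1(p)
    if p.part is LabPart.PART2:
        return windows_part2(p, include_transitions)
    return windows_part3(p)


# ---------------------------------------------------------------------------
# Protocol construction

_PART1_POOL = [
    (ActivityLabel.SITTING, ""),
    (ActivityLabel.STANDING, ""),
    (ActivityLabel.WALKING, "walking 80 bpm"),
    (ActivityLabel.WALKING, "walking 100 bpm"),
    (ActivityLabel.WALKING, "walking 120 bpm"),
    (ActivityLabel.WALKING, "jogging 140 bpm"),
]

_PART2_POOL = [
    (ActivityLabel.SITTING, "own pace"),
    (ActivityLabel.STANDING, "own pace"),
    (ActivityLabel.WALKING, "walking slowly"),
    (ActivityLabel.WALKING, "walking rapidly"),
    (ActivityLabel.WALKING, "jogging"),
]


def build_protocol(
    part: LabPart,
    order: list[int] | None = None,
    start: int = 0,
    repetitions: int = 2,
) -> LabProtocol:
    """Construct a protocol in a given (default: canonical) segment order.

    ``order`` permutes the part's activity pool for parts 1 and 2. Part 3
    ignores ``order`` and builds ``repetitions`` alternating sit-down/get-up
    cycles per transition pace (1, 2, 3 s); each 60-s cycle is one segment
    whose activity is the held posture.
    """
    if part is LabPart.PART3:
        segs = []
        for rep in range(repetitions):
            for pace in (1, 2, 3):
                segs.append(
                    ProtocolSegment(ActivityLabel.SITTING, 60, f"{pace}-s sit-down")
                )
                segs.append(
                    ProtocolSegment(ActivityLabel.STANDING, 60, f"{pace}-s get-up")
                )
        return LabProtocol(part, segs, start)
    pool = _PART1_POOL if part is LabPart.PART1 else _PART2_POOL
    duration = 180 if part is LabPart.PART1 else 120
    if order is None:
        order = list(range(len(pool)))
    if sorted(order) != list(range(len(pool))):
        raise ValueError(f"order must be a permutation of 0..{len(pool) - 1}")
    segs = [ProtocolSegment(pool[i][0], duration, pool[i][1]) for i in order]
    return LabProtocol(part, segs, start)


def randomize_protocol(part: LabPart, seed: int, start: int = 0) -> LabProtocol:
    """Draw a uniformly random segment order for a part (seed-deterministic).

    Parts 1 and 2 permute their activity pools uniformly. Part 3 keeps the
    mandatory sit-down/get-up alternation and shuffles which transition pace
    each cycle uses (each pace twice per direction).
    """
    rng = np.random.default_rng(seed)
    if part is LabPart.PART3:
        sit_paces = rng.permutation([1, 1, 2, 2, 3, 3])
        stand_paces = rng.permutation([1, 1, 2, 2, 3, 3])
        segs = []
        for i in range(6):
            segs.append(
                ProtocolSegment(ActivityLabel.SITTING, 60, f"{sit_paces[i]}-s sit-down")
            )
            segs.append(
                ProtocolSegment(ActivityLabel.STANDING, 60, f"{stand_paces[i]}-s get-up")
            )
        return LabProtocol(part, segs, start)
    pool = _PART1_POOL if part is LabPart.PART1 else _PART2_POOL
    order = list(rng.permutation(len(pool)))
    return build_protocol(part, order, start)


def protocol_to_reference(p: LabProtocol, w: AnalysisWindowSet) -> SecondStream:
    """Per-second reference labels from the planned segments, restricted to
    the analysis windows.

    This is the direct-observation stream an experimenter's protocol sheet
    implies: every emitted second carries the activity of the segment it
    falls in.
    """
    spans = p.segment_spans()
    if spans and w.windows:
        lo = min(lo for lo, _ in w.windows)
        hi = max(hi for _, hi in w.windows)
        if lo < spans[0][0] or hi > spans[-1][1]:
            raise ValueError("analysis windows extend beyond the protocol span")
    starts = np.asarray([s for s, _, _ in spans], dtype=np.int64)
    acts = np.asarray([a.value for _, _, a in spans], dtype=np.int8)
    times = np.concatenate(
        [np.arange(lo, hi, dtype=np.int64) for lo, hi in w.windows]
    ) if w.windows else np.empty(0, dtype=np.int64)
    seg_idx = np.searchsorted(starts, times, side="right") - 1
    codes = acts[seg_idx] if times.size else np.empty(0, dtype=np.int8)
    return SecondStream("protocol", "direct_observation", times, codes)
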