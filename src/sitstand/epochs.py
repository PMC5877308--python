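"""Core label algebra on 30-s epochs.

Posture trackers worn on the thigh classify fixed 30-s periods into sitting,
standing, walking, or idle. Reference instruments (direct observation logs,
inclinometer exports) yield per-second labels instead. This module provides
the harmonization layer both streams pass through before any scoring:

* second-to-epoch reduction with the dominance/priority tie-break,
* alignment and merging of two epoch streams (only periods registered by
  both devices are comparable),
* the day-level minimum-wear filter.

Epochs live on the absolute UTC 30-s grid (hh:mm:00 / hh:mm:30); timestamps
are integer UNIX seconds throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

EPOCH_SECONDS = 30


class ActivityLabel(Enum):
    """One posture/activity class per labeled interval.

    The integer codes double as the tie-break priority: when two or more
    activities dominate a 30-s window with equal second counts, the lowest
    code wins (sitting before standing before walking). IDLE is a valid
    device output but never a reference label; it ranks last in any tie.
    """

    SITTING = 0
    STANDING = 1
    WALKING = 2
    IDLE = 3

    def __str__(self) -> str:  # "sitting", not "ActivityLabel.SITTING"
        return self.name.lower()


#: The three reference-eligible activity classes, in tie-break priority order.
ACTIVITIES = (ActivityLabel.SITTING, ActivityLabel.STANDING, ActivityLabel.WALKING)

_LABEL_ALIASES = {
    "sitting": ActivityLabel.SITTING,
    "sit": ActivityLabel.SITTING,
    "standing": ActivityLabel.STANDING,
    "stand": ActivityLabel.STANDING,
    "walking": ActivityLabel.WALKING,
    "walk": ActivityLabel.WALKING,
    "idle": ActivityLabel.IDLE,
    "off": ActivityLabel.IDLE,
}


def parse_label(text: str) -> ActivityLabel:
    """Normalize a label string (case-insensitive; 'off' maps to IDLE).

    Unknown strings are a hard error, never coerced.
    """
    try:
        return _LABEL_ALIASES[text.strip().lower()]
    except KeyError:
        raise ValueError(f"unknown activity label: {text!r}") from None


class MalformedWindowError(ValueError):
    """A reduction window does not cover exactly one 30-s grid epoch."""


class GridMismatchError(ValueError):
    """Two epoch series are not on the same 30-s grid or subject."""


@dataclass(frozen=True)
class LabeledEpoch:
    """A half-open 30-s period [start, start+30) carrying one label."""

    start: int  # UNIX seconds, UTC, multiple of 30
    label: ActivityLabel
    duration: int = EPOCH_SECONDS

    def __post_init__(self) -> None:
        if self.start % EPOCH_SECONDS != 0:
            raise GridMismatchError(
                f"epoch start {self.start} not aligned to the {EPOCH_SECONDS}-s grid"
            )
        if self.duration != EPOCH_SECONDS:
            raise ValueError("epoch duration is fixed at 30 s")


def _as_code_array(labels) -> np.ndarray:
    out = np.asarray(
        [lab.value if isinstance(lab, ActivityLabel) else int(lab) for lab in labels],
        dtype=np.int8,
    )
    if out.size and (out.min() < 0 or out.max() > 3):
        raise ValueError("label codes must be in 0..3")
    return out


@dataclass
class EpochSeries:
    """Ordered 30-s epochs for one subject from one source.

    Gaps (missing epochs) are allowed; duplicate or unsorted starts are not.
    """

    subject_id: str
    source: str
    starts: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    codes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int8))

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.codes = _as_code_array(self.codes)
        if self.starts.shape != self.codes.shape:
            raise ValueError("starts and codes must have equal length")
        if self.starts.size:
            if np.any(self.starts % EPOCH_SECONDS != 0):
                raise GridMismatchError("epoch starts must be multiples of 30 s")
            if np.any(np.diff(self.starts) <= 0):
                raise ValueError("epoch starts must be strictly increasing")

    def __len__(self) -> int:
        return int(self.starts.size)

    def __iter__(self):
        for s, c in zip(self.starts, self.codes):
            yield LabeledEpoch(int(s), ActivityLabel(int(c)))

    @property
    def labels(self) -> list[ActivityLabel]:
        return [ActivityLabel(int(c)) for c in self.codes]

    @classmethod
    def from_epochs(cls, subject_id: str, source: str, epochs) -> "EpochSeries":
        epochs = list(epochs)
        return cls(
            subject_id,
            source,
            np.asarray([e.start for e in epochs], dtype=np.int64),
            np.asarray([e.label.value for e in epochs], dtype=np.int8),
        )


@dataclass
class SecondStream:
    """Per-second labels for one subject (reference-style export).

    One record per covered second, strictly increasing; 'off' seconds are
    stored as IDLE codes. Gaps are legitimate and preserved.
    """

    subject_id: str
    source: str
    times: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    codes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int8))

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.int64)
        self.codes = _as_code_array(self.codes)
        if self.times.shape != self.codes.shape:
            raise ValueError("times and codes must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("second timestamps must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class MergedPairSeries:
    """Epochs registered by BOTH of two sources, with one label per source.

    ``dropped_a_only`` / ``dropped_b_only`` account for periods one tracker
    missed for technical reasons; those are excluded from every analysis.
    """

    subject_id: str
    source_a: str
    source_b: str
    starts: np.ndarray
    codes_a: np.ndarray
    codes_b: np.ndarray
    dropped_a_only: int = 0
    dropped_b_only: int = 0

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.codes_a = _as_code_array(self.codes_a)
        self.codes_b = _as_code_array(self.codes_b)
        if not (self.starts.shape == self.codes_a.shape == self.codes_b.shape):
            raise ValueError("starts and label arrays must have equal length")
        if self.starts.size and np.any(np.diff(self.starts) <= 0):
            raise ValueError("epoch starts must be strictly increasing")

    def __len__(self) -> int:
        return int(self.starts.size)

    @property
    def wear_minutes(self) -> float:
        return len(self) * EPOCH_SECONDS / 60.0


# ---------------------------------------------------------------------------
# Second-to-epoch reduction


def _window_counts(codes: np.ndarray) -> np.ndarray:
    return np.bincount(codes, minlength=4)


def _reduce_counts(counts: np.ndarray) -> tuple[int, bool]:
    """Dominance rule on per-label second totals.

    Returns (winning code, ambivalent?). The most dominant activity wins;
    ties among activity maxima fall back to the fixed priority
    sitting > standing > walking. Off/idle seconds can win only by strict
    majority over each activity and never via the tie-break.
    """
    act = counts[:3]
    top = act.max(initial=0)
    if counts[3] > top:
        return ActivityLabel.IDLE.value, False
    # np.argmax picks the first maximum, i.e. the highest-priority activity
    winner = int(np.argmax(act))
    ambivalent = top > 0 and int((act == top).sum()) >= 2
    return winner, ambivalent


def reduce_seconds_to_epoch(window) -> ActivityLabel:
    """Reduce 30 consecutive seconds of labels to the epoch's single label.

    ``window`` is a sequence of exactly 30 labels (ActivityLabel values or
    integer codes); 'off'/unlabeled seconds are represented as IDLE.

    Examples
    --------
    8 s sitting + 11 s standing + 11 s walking reduces to standing (the two
    dominant activities tie and standing outranks walking); a 10/10/10 split
    reduces to sitting.
    """
    codes = _as_code_array(window)
    if codes.size != EPOCH_SECONDS:
        raise MalformedWindowError(
            f"window must contain exactly {EPOCH_SECONDS} seconds, got {codes.size}"
        )
    winner, _ = _reduce_counts(_window_counts(codes))
    return ActivityLabel(winner)


def _grid_epochs(stream: SecondStream, grid_origin: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Label + tie flag for every fully covered grid epoch of a stream.

    Returns (epoch starts, winning codes, ambivalence flags). Partially
    covered boundary epochs (fewer than 30 recorded seconds) are dropped.
    """
    if grid_origin % 1 != 0:
        raise ValueError("grid origin must be a whole second")
    if len(stream) == 0:
        empty = np.empty(0, dtype=np.int64)
        return empty, np.empty(0, dtype=np.int8), np.empty(0, dtype=bool)
    rel = stream.times - grid_origin
    idx = rel // EPOCH_SECONDS
    uniq, inv, per_epoch = np.unique(idx, return_inverse=True, return_counts=True)
    counts = np.zeros((uniq.size, 4), dtype=np.int64)
    np.add.at(counts, (inv, stream.codes.astype(np.int64)), 1)
    full = per_epoch == EPOCH_SECONDS
    winners = np.empty(int(full.sum()), dtype=np.int8)
    ties = np.empty(int(full.sum()), dtype=bool)
    for i, row in enumerate(counts[full]):
        w, t = _reduce_counts(row)
        winners[i] = w
        ties[i] = t
    starts = grid_origin + uniq[full] * EPOCH_SECONDS
    return starts.astype(np.int64), winners, ties


def reduce_stream(stream: SecondStream, grid_origin: int = 0) -> EpochSeries:
    """Reduce a per-second stream onto the 30-s epoch grid.

    One labeled epoch is emitted per fully covered grid epoch; boundary
    epochs covered by fewer than 30 recorded seconds are dropped, mirroring
    the exclusion of late-initialization periods at day edges. The default
    origin 0 is the absolute UTC grid (UNIX time is hh:mm:00-aligned).
    """
    starts, winners, _ = _grid_epochs(stream, grid_origin)
    return EpochSeries(stream.subject_id, stream.source, starts, winners)


def count_ambivalent(stream: SecondStream, grid_origin: int = 0) -> tuple[int, float]:
    """Count reduced epochs whose label needed the priority tie-break.

    Returns ``(count, percentage of reduced epochs)``. An epoch is
    ambivalent when two or three activities share the maximal second count
    (e.g. 15 s sitting + 15 s standing, or a 10/10/10 three-way split).
    """
    starts, _, ties = _grid_epochs(stream, grid_origin)
    n = int(starts.size)
    count = int(ties.sum())
    return count, (100.0 * count / n if n else 0.0)


# ---------------------------------------------------------------------------
# Alignment, merging, wear filtering


def align_and_merge(a: EpochSeries, b: EpochSeries) -> MergedPairSeries:
    """Keep only epochs registered by both sources.

    If one tracker did not register a 30-s period for technical reasons the
    period is excluded; the per-source drop counts are recorded on the
    result so exclusion bookkeeping survives into reports.
    """
    if a.subject_id != b.subject_id:
        raise GridMismatchError(
            f"cannot merge different subjects: {a.subject_id!r} vs {b.subject_id!r}"
        )
    common, ia, ib = np.intersect1d(a.starts, b.starts, return_indices=True)
    return MergedPairSeries(
        subject_id=a.subject_id,
        source_a=a.source,
        source_b=b.source,
        starts=common,
        codes_a=a.codes[ia],
        codes_b=b.codes[ib],
        dropped_a_only=len(a) - common.size,
        dropped_b_only=len(b) - common.size,
    )


def split_by_day(merged: MergedPairSeries, tz_offset_hours: float = 0.0):
    """Split a merged series into local calendar days.

    Yields ``(day_index, MergedPairSeries)`` where day_index counts days
    since the UNIX epoch in the subject's local time.
    """
    if len(merged) == 0:
        return
    local = merged.starts + int(round(tz_offset_hours * 3600))
    day = local // 86400
    for d in np.unique(day):
        m = day == d
        yield int(d), MergedPairSeries(
            merged.subject_id,
            merged.source_a,
            merged.source_b,
            merged.starts[m],
            merged.codes_a[m],
            merged.codes_b[m],
        )


def wear_filter(
    merged: MergedPairSeries,
    min_wear_minutes: float = 300.0,
    tz_offset_hours: float = 0.0,
) -> tuple[list[tuple[int, MergedPairSeries]], list[tuple[int, float]]]:
    """Retain local calendar days with enough matched wear time.

    A day is kept iff both trackers registered at least ``min_wear_minutes``
    of merged epochs (default 300 min = 5 h; exactly 5 h is retained, days
    with *less* are excluded). Returns ``(retained, excluded)`` where
    ``excluded`` lists ``(day_index, wear_minutes)`` for the dropped days.
    """
    retained: list[tuple[int, MergedPairSeries]] = []
    excluded: list[tuple[int, float]] = []
    for day, series in split_by_day(merged, tz_offset_hours):
        if series.wear_minutes >= min_wear_minutes:
            retained.append((day, series))
        else:
            excluded.append((day, series.wear_minutes))
    return retained, excluded
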