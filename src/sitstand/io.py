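"""Readers and writers for the pipeline's plain-text exchange formats.

* device epoch CSV — one row per 30-s period: ISO-8601 UTC timestamp,
  opaque user id, and one-hot boolean activity flags (all false = idle);
* per-second stream CSV — timestamp + label (``off`` marks unworn/idle
  seconds);
* protocol JSON — ordered planned segments per lab part;
* misallocation-profile JSON — the nine published-style percentages, so a
  printed profile can be reused without any raw data;
* detected-minutes JSON and tidy report CSV/JSON.

Readers validate against the type invariants and report offending line
numbers; writers produce canonical files that round-trip byte-stably.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .epochs import (
    ACTIVITIES,
    EPOCH_SECONDS,
    ActivityLabel,
    EpochSeries,
    SecondStream,
    parse_label,
)
from .metrics import MisallocationProfile
from .protocols import LabPart, LabProtocol, ProtocolSegment
from .reallocation import ActivityMinutes

_TRUE = {"yes", "true", "1", "y"}
_FALSE = {"no", "false", "0", "n", ""}


class InputValidationError(ValueError):
    """Malformed input file; the message names the offending line."""


def _parse_bool(value, line: int, column: str) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise InputValidationError(f"line {line}: {column}={value!r} is not a boolean")


def _parse_utc_seconds(value, line: int) -> int:
    try:
        ts = pd.Timestamp(str(value))
    except (ValueError, TypeError):
        raise InputValidationError(
            f"line {line}: unparseable timestamp {value!r}"
        ) from None
    if ts.tzinfo is None:
        ts = ts.tz_localize("UTC")
    return int(ts.timestamp())


def _iso(seconds: int) -> str:
    return pd.Timestamp(seconds, unit="s", tz="UTC").strftime("%Y-%m-%dT%H:%M:%SZ")


# ---------------------------------------------------------------------------
# Device epoch CSV

EPOCH_COLUMNS = ["timestamp", "user_id", "sitting", "standing", "walking"]


def read_device_epochs(path) -> EpochSeries:
    """Read a device epoch export.

    Timestamps are floored to the 30-s grid. Exactly zero or one activity
    flag may be true per row (all false means an idle period); two flags,
    an unparseable timestamp, or a duplicate period are hard errors naming
    the line.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in EPOCH_COLUMNS if c not in df.columns]
    if missing:
        raise InputValidationError(f"missing columns: {', '.join(missing)}")
    starts, codes = [], []
    seen: dict[int, int] = {}
    subject = None
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        t = _parse_utc_seconds(getattr(row, "timestamp"), line)
        t -= t % EPOCH_SECONDS
        flags = [
            _parse_bool(getattr(row, str(a)), line, str(a)) for a in ACTIVITIES
        ]
        if sum(flags) > 1:
            raise InputValidationError(
                f"line {line}: more than one activity flag is true"
            )
        if t in seen:
            raise InputValidationError(
                f"line {line}: duplicate 30-s period (same as line {seen[t]})"
            )
        seen[t] = line
        uid = getattr(row, "user_id")
        if subject is None:
            subject = uid
        elif uid != subject:
            raise InputValidationError(
                f"line {line}: multiple user ids in one file ({subject!r}, {uid!r})"
            )
        code = flags.index(True) if any(flags) else ActivityLabel.IDLE.value
        starts.append(t)
        codes.append(code)
    order = np.argsort(starts, kind="stable")
    return EpochSeries(
        subject or "unknown",
        str(Path(path).stem),
        np.asarray(starts, dtype=np.int64)[order],
        np.asarray(codes, dtype=np.int8)[order],
    )


def write_device_epochs(series: EpochSeries, path) -> None:
    rows = []
    for s, c in zip(series.starts, series.codes):
        lab = ActivityLabel(int(c))
        rows.append(
            {
                "timestamp": _iso(int(s)),
                "user_id": series.subject_id,
                "sitting": str(lab is ActivityLabel.SITTING).lower(),
                "standing": str(lab is ActivityLabel.STANDING).lower(),
                "walking": str(lab is ActivityLabel.WALKING).lower(),
            }
        )
    pd.DataFrame(rows, columns=EPOCH_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Per-second stream CSV


def read_second_stream(path, subject_id: str | None = None) -> SecondStream:
    """Read a per-second label stream (timestamp, label).

    Labels are case-insensitive; ``off`` marks idle/unworn seconds. Gaps
    between timestamps are preserved, never interpolated.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    for col in ("timestamp", "label"):
        if col not in df.columns:
            raise InputValidationError(f"missing column: {col}")
    times, codes = [], []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        times.append(_parse_utc_seconds(getattr(row, "timestamp"), line))
        try:
            codes.append(parse_label(getattr(row, "label")).value)
        except ValueError as e:
            raise InputValidationError(f"line {line}: {e}") from None
    t = np.asarray(times, dtype=np.int64)
    if t.size > 1 and np.any(np.diff(t) <= 0):
        bad = int(np.argmax(np.diff(t) <= 0)) + 3
        raise InputValidationError(f"line {bad}: timestamps not strictly increasing")
    return SecondStream(
        subject_id or str(Path(path).stem),
        str(Path(path).stem),
        t,
        np.asarray(codes, dtype=np.int8),
    )


def write_second_stream(stream: SecondStream, path) -> None:
    labels = [
        "off" if c == ActivityLabel.IDLE.value else str(ActivityLabel(int(c)))
        for c in stream.codes
    ]
    pd.DataFrame(
        {"timestamp": [_iso(int(t)) for t in stream.times], "label": labels}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Protocol JSON


def read_protocol(path) -> LabProtocol:
    with open(path) as f:
        obj = json.load(f)
    try:
        part = LabPart[obj["part"]]
        start = int(obj.get("start", 0))
        segs = [
            ProtocolSegment(
                parse_label(s["activity"]),
                int(s["planned_seconds"]),
                s.get("pace_note", ""),
            )
            for s in sorted(obj["segments"], key=lambda s: s["order_index"])
        ]
    except (KeyError, ValueError) as e:
        raise InputValidationError(f"malformed protocol file: {e}") from None
    return LabProtocol(part, segs, start)


def write_protocol(p: LabProtocol, path) -> None:
    obj = {
        "part": p.part.name,
        "start": p.start,
        "segments": [
            {
                "order_index": i,
                "activity": str(s.activity),
                "planned_seconds": s.planned_duration,
                "pace_note": s.pace_note,
            }
            for i, s in enumerate(p.segments)
        ],
    }
    Path(path).write_text(json.dumps(obj, indent=2) + "\n")


# ---------------------------------------------------------------------------
# Misallocation profile JSON


def read_profile(path) -> MisallocationProfile:
    """Read a profile file: ``{"ppr": {...}, "split": {detected: {actual: pct}}}``."""
    with open(path) as f:
        obj = json.load(f)
    try:
        ppr = {parse_label(k): (None if v is None else float(v))
               for k, v in obj["ppr"].items()}
        split = {
            parse_label(d): {
                parse_label(a): (None if v is None else float(v))
                for a, v in entries.items()
            }
            for d, entries in obj["split"].items()
        }
    except (KeyError, ValueError) as e:
        raise InputValidationError(f"malformed profile file: {e}") from None
    return MisallocationProfile(ppr, split)


def write_profile(profile: MisallocationProfile, path) -> None:
    obj = {
        "ppr": {str(a): profile.ppr.get(a) for a in ACTIVITIES},
        "split": {
            str(d): {str(a): v for a, v in profile.split.get(d, {}).items()}
            for d in ACTIVITIES
        },
    }
    Path(path).write_text(json.dumps(obj, indent=2) + "\n")


# ---------------------------------------------------------------------------
# Minutes JSON and reports


def read_minutes(path) -> tuple[ActivityMinutes, float | None]:
    """Read detected minutes: ``{"sitting": .., "standing": .., "walking": ..,
    "wear_minutes": ..}`` (wear optional)."""
    with open(path) as f:
        obj = json.load(f)
    try:
        minutes = ActivityMinutes(
            float(obj["sitting"]), float(obj["standing"]), float(obj["walking"])
        )
    except (KeyError, ValueError) as e:
        raise InputValidationError(f"malformed minutes file: {e}") from None
    wear = obj.get("wear_minutes")
    return minutes, (None if wear is None else float(wear))


def write_report_csv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["value"] = out["value"].map(
        lambda v: "" if pd.isna(v) else f"{v:.1f}"
    )
    out.to_csv(path, index=False)


def write_report_json(df: pd.DataFrame, path) -> None:
    records = [
        {
            "part": r.part,
            "activity": r.activity,
            "metric": r.metric,
            "value": None if pd.isna(r.value) else round(float(r.value), 1),
        }
        for r in df.itertuples(index=False)
    ]
    Path(path).write_text(json.dumps(records, indent=2) + "\n")
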