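"""Misclassification-reallocation correction of detected activity minutes.

A criterion device with imperfect precision inflates some activities and
deflates others. If a calibration sub-study provides, for each *detected*
activity d, its positive predictive rate PPR_d and the split of its false
positives by the activity actually performed, then every detected minute
can be reallocated to its likely actual activity:

    estimated_actual_a = PPR_a * Detected_a
                         + sum over d != a of
                           (100% - PPR_d) * (a_as_d split) * Detected_d

i.e. the correctly detected share of a's own minutes plus the shares of the
other activities' detected minutes that were actually a. When each split
sums to exactly 100%, total minutes are conserved. The profile is only
transportable to the target data insofar as the calibration activity mix
resembles it; the estimator itself is scale-free and applies equally to
per-day or mean-level minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

from .epochs import ACTIVITIES, ActivityLabel
from .metrics import MisallocationProfile, round_half_up


@dataclass(frozen=True)
class ActivityMinutes:
    """Minutes of sitting/standing/walking (detected or estimated)."""

    sitting: float
    standing: float
    walking: float

    def __post_init__(self) -> None:
        for name, v in vars(self).items():
            if not (v >= 0.0 and v == v and v != float("inf")):
                raise ValueError(f"{name} minutes must be finite and >= 0, got {v}")

    @property
    def total(self) -> float:
        return self.sitting + self.standing + self.walking

    def get(self, a: ActivityLabel) -> float:
        return getattr(self, str(a))

    def rounded(self) -> "ActivityMinutes":
        """Integer minutes, half away from zero (report convention)."""
        return ActivityMinutes(
            round_half_up(self.sitting, 0),
            round_half_up(self.standing, 0),
            round_half_up(self.walking, 0),
        )


@dataclass(frozen=True)
class ActivityShares:
    """Percentages of wear time per activity.

    For full-coverage data the three shares sum to ~100; degenerate inputs
    (e.g. no registered activity) legitimately sum to less.
    """

    sitting: float
    standing: float
    walking: float

    def get(self, a: ActivityLabel) -> float:
        return getattr(self, str(a))

    @property
    def total(self) -> float:
        return self.sitting + self.standing + self.walking

    def rounded(self, decimals: int = 1) -> "ActivityShares":
        return ActivityShares(
            round_half_up(self.sitting, decimals),
            round_half_up(self.standing, decimals),
            round_half_up(self.walking, decimals),
        )


def estimate_actual(
    detected: ActivityMinutes, profile: MisallocationProfile
) -> ActivityMinutes:
    """Reallocate detected minutes into an estimated actual distribution.

    Each actual activity receives the correctly detected fraction of its own
    minutes (PPR) plus, from every other detected activity d, the fraction
    (100% - PPR_d) of d's minutes weighted by the share of d's false
    positives attributed to it. Minutes are returned unrounded; round at
    report time with :meth:`ActivityMinutes.rounded`.

    An undefined split (no false positives in the calibration data) is
    only acceptable when the corresponding PPR is 100%, in which case it
    carries no mass.
    """
    for d in ACTIVITIES:
        if profile.ppr.get(d) is None:
            raise ValueError(f"profile is missing the PPR for detected {d}")
    est = {}
    for a in ACTIVITIES:
        value = profile.ppr[a] / 100.0 * detected.get(a)
        for d in ACTIVITIES:
            if d is a:
                continue
            leak = (100.0 - profile.ppr[d]) / 100.0
            share = profile.split[d].get(a)
            if share is None:
                if leak * detected.get(d) > 0.0:
                    raise ValueError(
                        f"split for detected {d} undefined but PPR < 100%"
                    )
                continue
            value += leak * (share / 100.0) * detected.get(d)
        est[str(a)] = value
    return ActivityMinutes(**est)


def shares(minutes: ActivityMinutes, wear_minutes: float) -> ActivityShares:
    """Activity distribution as percentages of matched wear time.

    Minutes are integer-rounded first and then divided by wear time, the
    convention the printed per-day tables follow.
    """
    if wear_minutes <= 0:
        raise ValueError("wear_minutes must be positive")
    r = minutes.rounded()
    return ActivityShares(
        100.0 * r.sitting / wear_minutes,
        100.0 * r.standing / wear_minutes,
        100.0 * r.walking / wear_minutes,
    )


def compare_distributions(
    a: ActivityShares, b: ActivityShares
) -> dict[ActivityLabel, float]:
    """Per-activity absolute difference in percentage points."""
    return {act: abs(a.get(act) - b.get(act)) for act in ACTIVITIES}
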