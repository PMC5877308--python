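"""One-vs-rest confusion performance and misallocation profiles.

Device validation here is epoch-wise: each merged 30-s period contributes
one (reference, predicted) label pair. A full 3x4 contingency table
(reference sitting/standing/walking x predicted sitting/standing/walking/
idle) is the common source from which everything else is marginalized:

* one-vs-rest TP/FP/FN/TN per activity, where an idle prediction is a miss
  (FN) for the reference activity and a correct rejection (TN) elsewhere;
* sensitivity, specificity, positive and negative predictive rate;
* the misallocation profile — per *detected* activity, its precision (PPR)
  and the breakdown of its false positives by the activity actually
  performed — which parameterizes the reallocation estimator.

Percentages are kept unrounded internally; reports round to one decimal,
half away from zero. A zero denominator yields ``None`` (an explicit
undefined marker), never 0 or 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .epochs import ACTIVITIES, ActivityLabel, MergedPairSeries

PRED_LABELS = ACTIVITIES + (ActivityLabel.IDLE,)


class InvalidReferenceError(ValueError):
    """A reference (true-condition) label was IDLE or otherwise invalid."""


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero (printed-report style: 0.05 -> 0.1)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CrossTab:
    """Reference x prediction contingency table over merged epochs.

    Rows: sitting/standing/walking (reference). Columns: the same three
    plus idle (prediction). Counts are epoch counts.
    """

    counts: np.ndarray  # shape (3, 4), int64

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (3, 4):
            raise ValueError("cross-tab must be 3 reference x 4 prediction labels")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __getitem__(self, key: tuple[ActivityLabel, ActivityLabel]) -> int:
        ref, pred = key
        if ref not in ACTIVITIES:
            raise InvalidReferenceError(f"{ref} is not a reference label")
        return int(self.counts[ref.value, pred.value])

    def __add__(self, other: "CrossTab") -> "CrossTab":
        return CrossTab(self.counts + other.counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index([str(a) for a in ACTIVITIES], name="reference"),
            columns=pd.Index([str(p) for p in PRED_LABELS], name="predicted"),
        )


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest positives/negatives for a single target activity."""

    target: ActivityLabel
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class PerformanceValues:
    """Sensitivity, specificity, PPR (precision) and NPR, in percent.

    ``None`` marks a value whose denominator was zero; it must survive into
    reports rather than being dropped or coerced.
    """

    sensitivity: float | None
    specificity: float | None
    ppr: float | None
    npr: float | None

    def rounded(self, decimals: int = 1) -> dict[str, float | None]:
        return {
            k: (None if v is None else round_half_up(v, decimals))
            for k, v in vars(self).items()
        }


def cross_tab(
    pairs,
    windows=None,
    *,
    reference: str = "a",
) -> CrossTab:
    """Tally the reference x prediction table from merged epoch pairs.

    ``pairs`` is a :class:`MergedPairSeries` (``reference`` names which side,
    'a' or 'b', is the criterion) or a pair of equal-length label sequences
    ``(reference_labels, predicted_labels)``. With an ``windows`` argument
    (an :class:`~sitstand.protocols.AnalysisWindowSet`), only epochs whose
    start lies inside the windows are counted.

    Reference labels must be sitting/standing/walking; an IDLE reference is
    an error. IDLE predictions are counted in the idle column.
    """
    if isinstance(pairs, MergedPairSeries):
        ref = pairs.codes_a if reference == "a" else pairs.codes_b
        pred = pairs.codes_b if reference == "a" else pairs.codes_a
        starts = pairs.starts
    else:
        ref_seq, pred_seq = pairs
        ref = np.asarray([getattr(x, "value", x) for x in ref_seq], dtype=np.int8)
        pred = np.asarray([getattr(x, "value", x) for x in pred_seq], dtype=np.int8)
        starts = None
    if ref.shape != pred.shape:
        raise ValueError("reference and prediction must have equal length")
    if windows is not None:
        if starts is None:
            raise ValueError("window restriction requires epoch start times")
        keep = np.isin(starts, windows.epoch_starts())
        ref, pred = ref[keep], pred[keep]
    if np.any(ref == ActivityLabel.IDLE.value):
        raise InvalidReferenceError("IDLE cannot be a reference label")
    counts = np.zeros((3, 4), dtype=np.int64)
    np.add.at(counts, (ref.astype(np.int64), pred.astype(np.int64)), 1)
    return CrossTab(counts)


def one_vs_rest(ct: CrossTab, target: ActivityLabel) -> ConfusionCounts:
    """Collapse the table to the target-vs-rest confusion counts.

    Idle predictions fall into FN for the reference activity (they are
    never a positive detection of anything) and into TN for every other
    target.
    """
    if target not in ACTIVITIES:
        raise InvalidReferenceError(f"{target} is not a scoreable activity")
    t = target.value
    tp = int(ct.counts[t, t])
    fn = int(ct.counts[t, :].sum()) - tp
    fp = int(ct.counts[:, t].sum()) - tp
    tn = ct.total - tp - fn - fp
    return ConfusionCounts(target, tp, fp, fn, tn)


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def performance(cc: ConfusionCounts) -> PerformanceValues:
    """The four performance percentages.

    sensitivity = TP/(TP+FN); specificity = TN/(TN+FP);
    PPR = TP/(TP+FP); NPR = TN/(TN+FN).
    """
    return PerformanceValues(
        sensitivity=_ratio(cc.tp, cc.tp + cc.fn),
        specificity=_ratio(cc.tn, cc.tn + cc.fp),
        ppr=_ratio(cc.tp, cc.tp + cc.fp),
        npr=_ratio(cc.tn, cc.tn + cc.fn),
    )


@dataclass
class MisallocationProfile:
    """Per detected activity: its PPR and the actual-activity split of its
    false positives.

    ``ppr[d]`` is the percentage of detected-d epochs that were actually d.
    ``split[d][a]`` (a != d) is the percentage of *wrongly* detected-d
    epochs during which the person was actually doing a; each defined split
    sums to 100 within printed-rounding slack. All entries are on the 0-100
    scale; ``None`` marks a split with no false positives to decompose.
    """

    ppr: dict[ActivityLabel, float | None]
    split: dict[ActivityLabel, dict[ActivityLabel, float | None]]

    SPLIT_SUM_SLACK = 0.2  # pct points; absorbs one-decimal printed rounding

    def __post_init__(self) -> None:
        for d in ACTIVITIES:
            p = self.ppr.get(d)
            if p is not None and not 0.0 <= p <= 100.0:
                raise ValueError(f"PPR for {d} out of [0, 100]: {p}")
            entries = self.split.get(d, {})
            vals = [entries.get(a) for a in ACTIVITIES if a is not d]
            if any(v is not None for v in vals):
                if any(v is None for v in vals):
                    raise ValueError(f"partial split for detected {d}")
                if any(not 0.0 <= v <= 100.0 for v in vals):
                    raise ValueError(f"split entries for {d} out of [0, 100]")
                s = sum(vals)
                if abs(s - 100.0) > self.SPLIT_SUM_SLACK:
                    raise ValueError(
                        f"split for detected {d} sums to {s:.2f}, not 100"
                    )

    @classmethod
    def from_percentages(
        cls,
        ppr_sitting: float,
        ppr_standing: float,
        ppr_walking: float,
        standing_as_sitting: float,
        walking_as_sitting: float,
        sitting_as_standing: float,
        walking_as_standing: float,
        standing_as_walking: float,
        sitting_as_walking: float,
    ) -> "MisallocationProfile":
        """Build from the nine published-style percentages.

        ``X_as_Y`` reads: among wrongly detected Y, the share actually X.
        """
        sit, sta, wal = ACTIVITIES
        return cls(
            ppr={sit: ppr_sitting, sta: ppr_standing, wal: ppr_walking},
            split={
                sit: {sta: standing_as_sitting, wal: walking_as_sitting},
                sta: {sit: sitting_as_standing, wal: walking_as_standing},
                wal: {sta: standing_as_walking, sit: sitting_as_walking},
            },
        )


def misdetection_decomposition(ct: CrossTab) -> MisallocationProfile:
    """Decompose each detected activity's false positives by actual activity.

    For detected activity d, the FP epochs are the off-diagonal entries of
    column d; their row shares (in percent) form the split, and the PPR
    comes from the one-vs-rest counts. A column with no false positives
    gets an all-``None`` split.
    """
    ppr: dict[ActivityLabel, float | None] = {}
    split: dict[ActivityLabel, dict[ActivityLabel, float | None]] = {}
    for d in ACTIVITIES:
        ppr[d] = performance(one_vs_rest(ct, d)).ppr
        others = [a for a in ACTIVITIES if a is not d]
        fp = {a: int(ct.counts[a.value, d.value]) for a in others}
        total = sum(fp.values())
        split[d] = {
            a: (None if total == 0 else 100.0 * fp[a] / total) for a in others
        }
    return MisallocationProfile(ppr, split)


def sensitivity_decomposition(
    ct: CrossTab,
) -> dict[ActivityLabel, dict[ActivityLabel, float | None]]:
    """Decompose each actual activity's misses by what was predicted instead.

    For reference activity a, the FN epochs are the off-diagonal entries of
    row a (wrong activities and idle); returned as percentages of the FN
    total, or all ``None`` when the activity was never missed.
    """
    out: dict[ActivityLabel, dict[ActivityLabel, float | None]] = {}
    for a in ACTIVITIES:
        others = [p for p in PRED_LABELS if p is not a]
        fn = {p: int(ct.counts[a.value, p.value]) for p in others}
        total = sum(fn.values())
        out[a] = {p: (None if total == 0 else 100.0 * fn[p] / total) for p in others}
    return out


def pooled_report(tabs: dict[str, CrossTab]) -> pd.DataFrame:
    """Per-part and pooled performance table.

    The ``all`` rows are computed from the elementwise sum of the per-part
    tables — pooled epoch counts, not averaged percentages. Returns a tidy
    frame keyed by (part, activity, metric) with one-decimal values
    (``NaN`` for undefined).
    """
    if not tabs:
        raise ValueError("no cross-tabs to report")
    items = list(tabs.items())
    if len(items) > 1:
        pooled = items[0][1]
        for _, t in items[1:]:
            pooled = pooled + t
        items.append(("all", pooled))
    rows = []
    for part, ct in items:
        for act in ACTIVITIES:
            vals = performance(one_vs_rest(ct, act)).rounded()
            for metric, value in vals.items():
                rows.append(
                    {
                        "part": part,
                        "activity": str(act),
                        "metric": metric,
                        "value": np.nan if value is None else value,
                    }
                )
    return pd.DataFrame(rows, columns=["part", "activity", "metric", "value"])
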