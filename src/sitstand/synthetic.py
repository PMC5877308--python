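"""Synthetic truth streams and imperfect device observations.

The validation pipeline needs ground truth it can never have in the field:
a per-second activity stream plus device outputs whose error structure is
known exactly. Two generators provide it:

* **free-living days** — an alternating-bout (semi-Markov) process over
  sitting/standing/walking with heavy-tailed (lognormal) bout durations and
  a stationary activity mix calibrated to a target share triple;
* **lab sessions** — truth that follows a scripted protocol, with posture
  changes completing within a few seconds of each segment boundary.

A :class:`DeviceErrorModel` then observes any truth stream on the 30-s
epoch grid: each epoch's true label is corrupted through a per-epoch
confusion matrix, epochs overlapping a truth transition can additionally be
blurred, and a small dropout rate deletes epochs entirely (unexplained
device lapses). Everything is seed-deterministic and carries provenance.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .epochs import (
    ACTIVITIES,
    EPOCH_SECONDS,
    ActivityLabel,
    EpochSeries,
    SecondStream,
)
from .metrics import CrossTab
from .protocols import (
    MAX_TRANSITION_SECONDS,
    AnalysisWindowSet,
    LabPart,
    LabProtocol,
    derive_windows,
    randomize_protocol,
)


@dataclass(frozen=True)
class BoutModel:
    """Alternating-bout model of a free-living day.

    ``mix`` is the stationary share of wear time per activity (sums to 1);
    ``mean_bout_minutes`` the mean duration of one bout of each activity.
    ``family`` is 'lognormal' (dispersion ``sigma`` on the log scale, the
    heavy-tailed shape typical of sitting bouts) or 'exponential'.
    """

    mix: tuple[float, float, float] = (0.57, 0.28, 0.15)
    mean_bout_minutes: tuple[float, float, float] = (20.0, 8.0, 3.0)
    family: str = "lognormal"
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if abs(sum(self.mix) - 1.0) > 1e-9:
            raise ValueError("mix shares must sum to 1")
        if any(s < 0 for s in self.mix):
            raise ValueError("mix shares must be >= 0")
        if any(m <= 0 for m in self.mean_bout_minutes):
            raise ValueError("mean bout durations must be positive")
        if self.family not in ("lognormal", "exponential"):
            raise ValueError("family must be 'lognormal' or 'exponential'")


@dataclass(frozen=True)
class DeviceErrorModel:
    """Per-epoch observation error of a simulated tracker.

    ``confusion`` is row-stochastic over true x reported
    {sitting, standing, walking, idle}. ``transition_blur`` is the
    probability that an epoch overlapping a truth change is reported as a
    uniformly drawn wrong activity instead. ``dropout`` is the probability
    an epoch is not registered at all.
    """

    confusion: tuple = (
        (1.0, 0.0, 0.0, 0.0),
        (0.0, 1.0, 0.0, 0.0),
        (0.0, 0.0, 1.0, 0.0),
        (0.0, 0.0, 0.0, 1.0),
    )
    transition_blur: float = 0.5
    dropout: float = 0.008

    def __post_init__(self) -> None:
        C = self.matrix
        if C.shape != (4, 4) or np.any(C < 0) or not np.allclose(C.sum(axis=1), 1.0):
            raise ValueError("confusion must be 4x4 row-stochastic")
        if not 0.0 <= self.transition_blur <= 1.0:
            raise ValueError("transition_blur must be in [0, 1]")
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError("dropout must be in [0, 1]")

    @property
    def matrix(self) -> np.ndarray:
        return np.asarray(self.confusion, dtype=float)

    @classmethod
    def identity(cls, transition_blur: float = 0.0, dropout: float = 0.0):
        return cls(transition_blur=transition_blur, dropout=dropout)

    @classmethod
    def from_confusion(cls, C, transition_blur: float = 0.5, dropout: float = 0.008):
        C = np.asarray(C, dtype=float)
        return cls(tuple(map(tuple, C)), transition_blur, dropout)


#: Inclinometer-style criterion device: high precision, slight tendency to
#: confuse the static postures and to miss walking epochs as standing/idle.
CRITERION_ERROR = DeviceErrorModel.from_confusion(
    [
        [0.94, 0.04, 0.02, 0.00],
        [0.04, 0.92, 0.04, 0.00],
        [0.02, 0.06, 0.90, 0.02],
        [0.00, 0.00, 0.00, 1.00],
    ]
)

#: Consumer-tracker test device: weakest at distinguishing standing from
#: sitting, very reliable for walking.
TEST_DEVICE_ERROR = DeviceErrorModel.from_confusion(
    [
        [0.86, 0.10, 0.03, 0.01],
        [0.20, 0.75, 0.04, 0.01],
        [0.01, 0.01, 0.97, 0.01],
        [0.00, 0.00, 0.00, 1.00],
    ]
)


def _config_digest(*objs) -> str:
    h = hashlib.sha256()
    for o in objs:
        h.update(repr(o).encode())
    return h.hexdigest()[:12]


# ---------------------------------------------------------------------------
# Truth generators


def _embedded_weights(mix: np.ndarray, means: np.ndarray) -> np.ndarray:
    """Next-bout sampling weights whose no-self-transition chain has the
    stationary time shares ``mix``.

    Target embedded visit frequencies are t_a ~ mix_a / mean_a; because the
    chain forbids immediate repeats, the naive weights w = t are biased, so
    they are corrected by fixed-point iteration on the chain's stationary
    distribution.
    """
    t = mix / means
    pos = t > 0
    if pos.sum() <= 1:
        return t / t.sum()
    t = t / t.sum()
    w = t.copy()
    for _ in range(200):
        P = np.zeros((3, 3))
        for a in range(3):
            if not pos[a]:
                continue
            denom = w[pos].sum() - w[a]
            for b in range(3):
                if b != a and pos[b]:
                    P[a, b] = w[b] / denom
        # stationary distribution of P on the active states
        idx = np.where(pos)[0]
        A = P[np.ix_(idx, idx)].T - np.eye(idx.size)
        A[-1] = 1.0
        rhs = np.zeros(idx.size)
        rhs[-1] = 1.0
        pi = np.linalg.solve(A, rhs)
        full = np.zeros(3)
        full[idx] = pi
        new = np.where(pos, w * t / np.maximum(full, 1e-12), 0.0)
        new /= new.sum()
        if np.max(np.abs(new - w)) < 1e-12:
            w = new
            break
        w = new
    return w


def _bout_seconds(bm: BoutModel, code: int, rng: np.random.Generator) -> int:
    mean_s = bm.mean_bout_minutes[code] * 60.0
    if bm.family == "exponential":
        d = rng.exponential(mean_s)
    else:
        mu = np.log(mean_s) - bm.sigma**2 / 2.0
        d = rng.lognormal(mu, bm.sigma)
    return max(1, int(round(d)))


def simulate_free_living_day(
    bm: BoutModel,
    wear_minutes: float = 774.0,
    seed: int = 0,
    start: int = 0,
    subject_id: str = "sim",
) -> SecondStream:
    """One continuous free-living wear period as per-second truth labels.

    Bouts of sitting/standing/walking alternate (no bout is followed by the
    same activity); durations are drawn from the bout model and the day is
    truncated to exactly ``wear_minutes``. Deterministic per seed.
    """
    if wear_minutes <= 0:
        raise ValueError("wear_minutes must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(wear_minutes * 60))
    mix = np.asarray(bm.mix, dtype=float)
    means = np.asarray(bm.mean_bout_minutes, dtype=float)
    if np.count_nonzero(mix) == 1:
        code = int(np.argmax(mix))
        codes = np.full(n, code, dtype=np.int8)
        times = start + np.arange(n, dtype=np.int64)
        return SecondStream(subject_id, "truth", times, codes)
    w = _embedded_weights(mix, means)
    # first bout from the stationary time shares
    current = int(rng.choice(3, p=mix))
    out = np.empty(n, dtype=np.int8)
    filled = 0
    while filled < n:
        dur = min(_bout_seconds(bm, current, rng), n - filled)
        out[filled : filled + dur] = current
        filled += dur
        probs = w.copy()
        probs[current] = 0.0
        probs /= probs.sum()
        current = int(rng.choice(3, p=probs))
    times = start + np.arange(n, dtype=np.int64)
    return SecondStream(subject_id, "truth", times, out)


def simulate_lab_session(
    p: LabProtocol,
    transition_seconds: int = MAX_TRANSITION_SECONDS,
    seed: int = 0,
    subject_id: str = "sim",
) -> SecondStream:
    """Truth stream for a scripted lab session.

    The participant performs each segment's activity; at every segment
    boundary the actual posture change completes within a uniformly drawn
    0..``transition_seconds`` delay after the boundary (at most 5 s), so
    analysis windows — which keep clear of boundaries by construction —
    see pure activity.
    """
    if not 0 <= transition_seconds <= MAX_TRANSITION_SECONDS:
        raise ValueError(
            f"transition_seconds must be in 0..{MAX_TRANSITION_SECONDS}"
        )
    rng = np.random.default_rng(seed)
    spans = p.segment_spans()
    if not spans:
        return SecondStream(subject_id, "truth")
    t0, t1 = spans[0][0], spans[-1][1]
    times = np.arange(t0, t1, dtype=np.int64)
    codes = np.empty(times.size, dtype=np.int8)
    prev_act = spans[0][2]
    for lo, hi, act in spans:
        delay = 0 if act is prev_act else int(rng.integers(0, transition_seconds + 1))
        codes[lo - t0 : lo - t0 + delay] = prev_act.value
        codes[lo - t0 + delay : hi - t0] = act.value
        prev_act = act
    return SecondStream(subject_id, "truth", times, codes)


# ---------------------------------------------------------------------------
# Device observation


def _truth_epochs(truth: SecondStream, grid_origin: int = 0):
    """Reduce truth to grid epochs plus a flag for change-overlapping epochs.

    An epoch overlaps a change when its 30 truth seconds are not unanimous.
    Only fully covered epochs are returned.
    """
    from .epochs import _grid_epochs  # same reduction path as the pipeline

    starts, winners, _ = _grid_epochs(truth, grid_origin)
    if starts.size == 0:
        return starts, winners, np.empty(0, dtype=bool)
    # an epoch is non-unanimous iff some adjacent second pair inside it differs
    rel = (truth.times - grid_origin) // EPOCH_SECONDS
    differs = (truth.codes[1:] != truth.codes[:-1]) & (rel[1:] == rel[:-1])
    change_starts = np.unique(
        grid_origin + rel[1:][differs] * EPOCH_SECONDS
    )
    changed = np.isin(starts, change_starts)
    return starts, winners, changed


def observe_with_device(
    truth: SecondStream,
    em: DeviceErrorModel,
    seed: int = 0,
    grid_origin: int = 0,
    source: str = "device",
) -> EpochSeries:
    """Simulate a tracker's epoch export from a truth stream.

    Per fully covered grid epoch: the truth is reduced to one label; with
    probability ``transition_blur`` a change-overlapping epoch is reported
    as a uniformly drawn wrong activity; otherwise the reported label is a
    draw from the confusion row of the true label. Finally each epoch is
    dropped (unregistered) with probability ``dropout``.
    """
    rng = np.random.default_rng(seed)
    starts, true_codes, changed = _truth_epochs(truth, grid_origin)
    n = starts.size
    if n == 0:
        return EpochSeries(truth.subject_id, source)
    C = em.matrix
    reported = np.empty(n, dtype=np.int8)
    u = rng.random(n)
    blur_mask = changed & (u < em.transition_blur)
    for i in range(n):
        t = int(true_codes[i])
        if blur_mask[i]:
            wrong = [a.value for a in ACTIVITIES if a.value != t]
            reported[i] = int(rng.choice(wrong))
        else:
            reported[i] = int(rng.choice(4, p=C[t]))
    keep = rng.random(n) >= em.dropout
    return EpochSeries(truth.subject_id, source, starts[keep], reported[keep])


def expected_cross_tab(
    truth: SecondStream,
    em: DeviceErrorModel,
    windows: AnalysisWindowSet | None = None,
    grid_origin: int = 0,
) -> np.ndarray:
    """Analytic expectation of the reference x reported table.

    Expected epoch counts (before dropout, which thins all cells equally)
    for a device observing ``truth`` under ``em``, optionally restricted to
    analysis windows. Rows: true sitting/standing/walking; columns add idle.
    """
    starts, true_codes, changed = _truth_epochs(truth, grid_origin)
    if windows is not None:
        keep = np.isin(starts, windows.epoch_starts())
        true_codes, changed = true_codes[keep], changed[keep]
    C = em.matrix
    out = np.zeros((3, 4), dtype=float)
    for t, ch in zip(true_codes, changed):
        t = int(t)
        row = C[t].copy()
        if ch and em.transition_blur > 0:
            blurred = np.zeros(4)
            wrong = [a.value for a in ACTIVITIES if a.value != t]
            blurred[wrong] = 0.5
            row = (1 - em.transition_blur) * row + em.transition_blur * blurred
        out[t] += row
    return out


def implied_performance(C: np.ndarray, mix: np.ndarray) -> dict:
    """Performance values implied by a confusion matrix and activity mix.

    For an infinite sample with true-label shares ``mix`` (over the three
    activities) observed through row-stochastic ``C``, returns the
    sensitivity/specificity/PPR/NPR percentages per activity — the values
    empirical estimates converge to.
    """
    C = np.asarray(C, dtype=float)[:3]
    mix = np.asarray(mix, dtype=float)
    joint = mix[:, None] * C  # P(true=a, reported=d)
    out = {}
    for a in ACTIVITIES:
        i = a.value
        tp = joint[i, i]
        fn = joint[i].sum() - tp
        fp = joint[:, i].sum() - tp
        tn = joint.sum() - tp - fn - fp
        out[a] = {
            "sensitivity": 100.0 * tp / (tp + fn) if tp + fn else None,
            "specificity": 100.0 * tn / (tn + fp) if tn + fp else None,
            "ppr": 100.0 * tp / (tp + fp) if tp + fp else None,
            "npr": 100.0 * tn / (tn + fn) if tn + fn else None,
        }
    return out


# ---------------------------------------------------------------------------
# Wired scenarios


@dataclass
class SimSession:
    """A fully wired simulation scenario with analytic expectations."""

    truth: SecondStream
    devices: dict[str, EpochSeries]
    expected: dict[str, np.ndarray]  # expected 3x4 tables per device
    windows: AnalysisWindowSet | None
    protocol: LabProtocol | None
    provenance: dict = field(default_factory=dict)


SCENARIOS = ("LAB_PART1", "LAB_PART2", "LAB_PART3", "FREE_LIVING")


def make_validation_fixture(
    scenario: str,
    seed: int,
    criterion: DeviceErrorModel = CRITERION_ERROR,
    test_device: DeviceErrorModel = TEST_DEVICE_ERROR,
    bout_model: BoutModel = BoutModel(),
    wear_minutes: float = 774.0,
) -> SimSession:
    """Build a complete scenario: truth, two devices, expected confusion.

    Lab scenarios follow a seed-randomized protocol with transition-free
    analysis windows; the free-living scenario simulates one wear day.
    The expected tables are computed analytically from the truth epochs and
    each device's error model (restricted to the analysis windows for lab
    scenarios). Repeated seeds give bitwise-identical fixtures.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; pick one of {SCENARIOS}")
    ss = np.random.SeedSequence(seed)
    s_truth, s_crit, s_test = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3)]
    if scenario == "FREE_LIVING":
        protocol, windows = None, None
        truth = simulate_free_living_day(bout_model, wear_minutes, seed=s_truth)
    else:
        part = LabPart[scenario.replace("LAB_", "")]
        protocol = randomize_protocol(part, seed)
        windows = derive_windows(protocol, include_transitions=False)
        truth = simulate_lab_session(protocol, seed=s_truth)
    devices = {
        "criterion": observe_with_device(truth, criterion, s_crit, source="criterion"),
        "test": observe_with_device(truth, test_device, s_test, source="test"),
    }
    expected = {
        "criterion": expected_cross_tab(truth, criterion, windows),
        "test": expected_cross_tab(truth, test_device, windows),
    }
    return SimSession(
        truth=truth,
        devices=devices,
        expected=expected,
        windows=windows,
        protocol=protocol,
        provenance={
            "scenario": scenario,
            "seed": seed,
            "config": _config_digest(criterion, test_device, bout_model, wear_minutes),
        },
    )
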