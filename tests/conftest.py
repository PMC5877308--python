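import numpy as np
import pytest

from sitstand.epochs import ActivityLabel

SIT, STAND, WALK, IDLE = (
    ActivityLabel.SITTING,
    ActivityLabel.STANDING,
    ActivityLabel.WALKING,
    ActivityLabel.IDLE,
)


def brute_force_reduce(window):
    """Independent tally oracle for the 30-s dominance/priority rule.

    Counts seconds per label the naive way; off/idle wins only when it
    strictly exceeds every activity, otherwise the best activity wins with
    ties resolved sitting > standing > walking.
    """
    counts = {lab: 0 for lab in ActivityLabel}
    for second in window:
        counts[second] += 1
    best = None
    for lab in (SIT, STAND, WALK):  # priority order
        if best is None or counts[lab] > counts[best]:
            best = lab
    if counts[IDLE] > max(counts[SIT], counts[STAND], counts[WALK]):
        return IDLE
    return best


def random_window(rng, p_idle=0.2):
    """A random 30-s window of labels at 1-s granularity."""
    probs = [(1 - p_idle) / 3] * 3 + [p_idle]
    return [ActivityLabel(int(c)) for c in rng.choice(4, size=30, p=probs)]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
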