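import numpy as np
import pytest

from socialetho.core import Bout, BoutTable


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def random_bout_table(rng, n_bouts, n_actions=4, n_flies=2, duration=600.0):
    """Random (unstructured) bout table used for oracle-equivalence checks."""
    actions = [f"act{i}" for i in range(n_actions)]
    bouts = []
    for _ in range(n_bouts):
        start = rng.uniform(0, duration - 1)
        bouts.append(
            Bout(
                fly_id=f"fly{rng.integers(n_flies) + 1}",
                action=actions[rng.integers(n_actions)],
                start=start,
                stop=start + rng.uniform(0.01, 5.0),
            )
        )
    bouts.sort(key=lambda b: (b.fly_id, b.action, b.start))
    return BoutTable(
        trial_id="random",
        bouts=bouts,
        trial_duration=duration + 10,
        vocabulary=tuple(actions),
    )
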