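"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import re

import numpy as np
import pytest

from ethosleep import SimConfig, score_ethogram, simulate_fly


def oracle_sleep(immobile, masked, epoch_s=10.0, min_bout_s=300.0):
    """Independent regex formulation of the sleep rule.

    Epochs become symbols (I = immobile, m = masked, A = active); sleep
    bouts are maximal ``I[Im]*I`` (or single ``I``) stretches strictly
    longer than ``min_bout_s`` — masked epochs join runs but cannot start
    or end one.
    """
    s = "".join(
        "m" if mk else ("I" if im else "A") for im, mk in zip(immobile, masked)
    )
    asleep = np.zeros(len(s), dtype=bool)
    bouts = []
    for m in re.finditer(r"I[Im]*I|I", s):
        a, b = m.span()
        if (b - a) * epoch_s > min_bout_s:
            bouts.append((a * epoch_s, b * epoch_s))
            asleep[a:b] = True
    return asleep, bouts


@pytest.fixture(scope="session")
def female_fly_2d():
    """One default female fly, two days, scored with default thresholds."""
    series = simulate_fly(SimConfig(seed=1234, duration_h=48, sex="female"))
    return series, score_ethogram(series)


def spawn_seeds(master: int, n: int) -> list[int]:
    return [
        int(ss.generate_state(1)[0] % (2**31))
        for ss in np.random.SeedSequence(master).spawn(n)
    ]
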