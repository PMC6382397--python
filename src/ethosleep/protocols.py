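"""End-to-end experiment archetypes built from the simulator and the scorer.

``run_trigger_ladder`` reproduces the acute-deprivation design: a baseline
day, one night (ZT12-24) of closed-loop deprivation at each trigger length
of the ladder, and a rebound morning scored over ZT0-3 against same-seed
undisturbed counterfactual controls.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pandas as pd

from .ethogram import score_ethogram, window_sleep_min
from .homeostasis import ReboundModel
from .simulate import DEFAULT_TRIGGER_LADDER_S, SimConfig, simulate_deprivation

__all__ = ["run_trigger_ladder"]


def _score_fly(config, trigger_s, window):
    series, log = simulate_deprivation(config, trigger_s, window=window)
    eth = score_ethogram(series, stim=log, lights_on_s=config.lights_on_s)
    return eth, log


def run_trigger_ladder(
    config: SimConfig,
    triggers=DEFAULT_TRIGGER_LADDER_S,
    n_per_group: int = 10,
    seed: int | None = None,
    n_boot: int = 1000,
) -> pd.DataFrame:
    """Run the trigger ladder; one row per trigger length.

    The protocol spans 54 h: baseline day (B window ZT0-3 of day 0), a
    12-h deprivation night (ZT12-24 of day 1), and the rebound morning
    (R window ZT0-3 of day 2).  Sleep lost is the within-pair difference of
    night sleep between each deprived fly and its same-seed undisturbed
    twin; the rebound statistic H is calibrated on the undisturbed group.
    """
    seed = config.seed if seed is None else seed
    config = replace(config, duration_h=54.0, seed=seed)
    night = (36.0 * 3600.0, 48.0 * 3600.0)

    fly_seeds = [
        int(ss.generate_state(1)[0] % (2**31))
        for ss in np.random.SeedSequence(seed).spawn(n_per_group)
    ]

    # undisturbed counterfactual twins, shared across the whole ladder
    controls = []
    for fs in fly_seeds:
        eth, _ = _score_fly(replace(config, seed=fs), math.inf, None)
        controls.append(
            {
                "night_sleep": window_sleep_min(eth, (12.0, 24.0), 1),
                "b": window_sleep_min(eth, (0.0, 3.0), 0),
                "r": window_sleep_min(eth, (0.0, 3.0), 2),
            }
        )
    ctrl_pairs = [(c["b"], c["r"]) for c in controls]

    rows = []
    for trig in triggers:
        night_sleep, rotations, pairs = [], [], []
        for fs in fly_seeds:
            eth, log = _score_fly(replace(config, seed=fs), float(trig), night)
            night_sleep.append(window_sleep_min(eth, (12.0, 24.0), 1))
            rotations.append(len(log))
            pairs.append(
                (window_sleep_min(eth, (0.0, 3.0), 0), window_sleep_min(eth, (0.0, 3.0), 2))
            )
        res = ReboundModel(ctrl_pairs, pairs).fit(n_boot=n_boot, seed=seed + int(trig))
        lost = [c["night_sleep"] - s for c, s in zip(controls, night_sleep)]
        rows.append(
            {
                "trigger_s": float(trig),
                "n": n_per_group,
                "rotations_per_night": float(np.mean(rotations)),
                "night_sleep_min": float(np.mean(night_sleep)),
                "sleep_lost_min": float(np.mean(lost)),
                "mean_h_min": res.mean_h,
                "h_ci_lo": res.ci[0],
                "h_ci_hi": res.ci[1],
                "rebound_significant": res.significant,
            }
        )
    return pd.DataFrame(rows)
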