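"""Generative model of single-fly tracking data.

Behavior is an alternating-bout semi-Markov process: at each bout start a
state (quiescence / micromovement / walking) is drawn with weights modulated
by a bimodal circadian gain (activity peaks at lights-on and lights-off),
then a bout duration is drawn from a state-specific lognormal — heavy-tailed
for quiescence so that sleep episodes well beyond 300 s, up to the longest
deprivation triggers, occur naturally.  Bouts are then rasterised to 10-s
epochs as (position, maximal velocity) emissions:

* quiescence      — sub-threshold velocity, position frozen;
* micromovement   — supra-threshold velocity, ±1 mm in-place jitter, with
  probability ``food_attraction`` relocated to within 4 mm of the food;
* walking         — tube-spanning zigzag that crosses the midline every
  epoch (so a beam-crossing monitor always registers walking).

Closed-loop deprivation replays the same process under a monitor: once
continuous immobility reaches ``trigger_s`` a 1-s tube rotation is logged;
with probability ``compliance`` the quiescence bout is terminated and the
fly startles into ``post_rotation_arousal_s`` of locomotion, otherwise the
bout continues and the immobility clock restarts.  The rotation spins the
tube about its axis, so position is unchanged while measured velocity
spikes (which downstream scoring masks).

Determinism contract: identical (seed, config) produce bit-identical
output.  Cohort seeds derive from the master seed by counter-based
``SeedSequence.spawn``, so a cohort is reproducible under appending flies
at the end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .io import StimulusLog, TrackingSeries, zt

__all__ = [
    "SimConfig",
    "LifespanConfig",
    "ConfigError",
    "simulate_fly",
    "simulate_deprivation",
    "simulate_cohort",
    "circadian_gain",
    "expected_scored_sleep_fraction",
    "calibrate_quiescence_rate",
    "DEFAULT_TRIGGER_LADDER_S",
]

#: default trigger ladder for the acute-deprivation protocol, seconds
DEFAULT_TRIGGER_LADDER_S = (20, 40, 80, 140, 220, 340, 480, 660, 840, 1000)

_STATES = ("quiescence", "micromovement", "walking")


class ConfigError(ValueError):
    pass


def _default_rates(sex: str) -> dict:
    if sex == "male":
        return {"quiescence": 1.0, "micromovement": 1.6, "walking": 1.0}
    return {"quiescence": 1.0, "micromovement": 4.0, "walking": 1.2}


def _default_durations(sex: str) -> dict:
    # lognormal (mu, sigma) of bout duration in seconds
    q_med = 520.0 if sex == "male" else 360.0
    return {
        "quiescence": (math.log(q_med), 1.0),
        "micromovement": (math.log(150.0), 0.7),
        "walking": (math.log(60.0), 0.6),
    }


@dataclass
class SimConfig:
    seed: int = 0
    epoch_s: float = 10.0
    duration_h: float = 24.0
    tube_length_mm: float = 70.0
    lights_on_s: float = 0.0
    sex: str = "female"
    circadian_amplitude: float = 1.0
    state_rates: dict | None = None  # per-state bout-initiation weights
    bout_dur_params: dict | None = None  # per-state lognormal (mu, sigma), s
    indiv_quiescence_scale: float = 0.0  # sigma of lognormal individual effect
    indiv_effect: float | None = None  # explicit multiplier (same fly, new recording)
    food_attraction: float = 0.5  # P(micromovement bout relocates within 4 mm of food)
    mated: bool = False
    compliance: float = 0.9  # P(rotation interrupts the quiescence bout)
    post_rotation_arousal_s: float = 30.0

    def resolved_rates(self) -> dict:
        rates = dict(self.state_rates or _default_rates(self.sex))
        if self.mated:
            rates["micromovement"] *= 2.0
        return rates

    def resolved_durations(self) -> dict:
        return dict(self.bout_dur_params or _default_durations(self.sex))

    def resolved_food_attraction(self) -> float:
        return min(0.9, self.food_attraction + 0.3) if self.mated else self.food_attraction

    def validate(self) -> "SimConfig":
        if self.duration_h < 1:
            raise ConfigError("duration_h: must be >= 1 hour")
        if self.epoch_s <= 0:
            raise ConfigError("epoch_s: must be positive")
        if self.tube_length_mm <= 0:
            raise ConfigError("tube_length_mm: must be positive")
        if self.sex not in ("male", "female"):
            raise ConfigError(f"sex: unknown value {self.sex!r}")
        if self.circadian_amplitude < 0:
            raise ConfigError("circadian_amplitude: must be >= 0")
        if not 0.0 <= self.compliance <= 1.0:
            raise ConfigError("compliance: must be in [0, 1]")
        if not 0.0 <= self.food_attraction <= 1.0:
            raise ConfigError("food_attraction: must be in [0, 1]")
        if self.indiv_quiescence_scale < 0:
            raise ConfigError("indiv_quiescence_scale: must be >= 0")
        if self.post_rotation_arousal_s < 0:
            raise ConfigError("post_rotation_arousal_s: must be >= 0")
        rates = self.resolved_rates()
        durs = self.resolved_durations()
        for s in _STATES:
            if s not in rates or rates[s] < 0:
                raise ConfigError(f"state_rates: missing or negative weight for {s!r}")
            if s not in durs or durs[s][1] < 0:
                raise ConfigError(f"bout_dur_params: invalid parameters for {s!r}")
        if sum(rates.values()) <= 0:
            raise ConfigError("state_rates: all weights are zero")
        return self


@dataclass
class LifespanConfig:
    """Sex-specific Weibull lifespans, optionally shifted by sleep amount."""

    scale_days: dict = field(default_factory=lambda: {"male": 49.5, "female": 44.0})
    shape: dict = field(default_factory=lambda: {"male": 5.0, "female": 5.0})
    sleep_effect: float = 0.0  # days of life per hour of daily sleep
    censor_rate: float = 0.0

    def validate(self) -> "LifespanConfig":
        for sex in ("male", "female"):
            if self.scale_days.get(sex, 0) <= 0:
                raise ConfigError(f"scale_days: must be positive for {sex}")
            if self.shape.get(sex, 0) <= 0:
                raise ConfigError(f"shape: must be positive for {sex}")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ConfigError("censor_rate: must be in [0, 1)")
        return self


def circadian_gain(zt_h, amplitude: float):
    """Multiplicative activity gain >= 1: two von-Mises bumps at ZT0 and ZT12.

    The gain multiplies the active-state bout weights and divides the
    quiescence weight, so the odds of starting an active bout swing with
    the square of the gain — a sharp dawn/dusk drive with mid-day and
    mid-night troughs.  ``amplitude = 0`` gives a flat (clock-less) profile.
    """
    ang = np.asarray(zt_h, dtype=float) / 24.0 * 2.0 * np.pi
    bump = (np.exp(4.0 * np.cos(ang)) + np.exp(4.0 * np.cos(ang - np.pi))) / np.exp(4.0)
    return 1.0 + amplitude * bump


# ---------------------------------------------------------------------------
# bout process
# ---------------------------------------------------------------------------

def _draw_bouts(config, rng, trigger_s, window):
    """Run the semi-Markov process; returns (segments, rotation onsets).

    Segments are ``(kind, t0, t1)`` in continuous seconds with kind in
    {'Q','M','W','R'}; they tile [0, duration) exactly.
    """
    total = config.duration_h * 3600.0
    rates = config.resolved_rates()
    durs = config.resolved_durations()
    amp = config.circadian_amplitude

    if config.indiv_effect is not None:
        indiv = float(config.indiv_effect)
    elif config.indiv_quiescence_scale > 0:
        indiv = float(np.exp(rng.normal(0.0, config.indiv_quiescence_scale)))
    else:
        indiv = 1.0

    w0, w1 = (0.0, total) if window is None else window
    monitored = np.isfinite(trigger_s)

    segments: list[tuple[str, float, float]] = []
    rotations: list[float] = []
    t = 0.0
    imm_start: float | None = None  # onset of the ongoing continuous immobility
    prev_kind = None

    while t < total:
        g = float(circadian_gain(zt(t, config.lights_on_s), amp))
        wq = rates["quiescence"] * indiv / g
        wm = rates["micromovement"] * g
        ww = rates["walking"] * g
        # alternation: a quiescence bout is followed by an active bout
        # whenever one is reachable, so quiescence runs are single bouts
        if prev_kind == "Q" and (wm + ww) > 0:
            wq = 0.0
        u = rng.random() * (wq + wm + ww)
        if u < wq:
            kind = "Q"
            mu, sg = durs["quiescence"]
        elif u < wq + wm:
            kind = "M"
            mu, sg = durs["micromovement"]
        else:
            kind = "W"
            mu, sg = durs["walking"]
        dur = float(rng.lognormal(mu, sg)) if sg > 0 else math.exp(mu)
        end = min(t + dur, total)

        if kind != "Q":
            if end > t:
                segments.append((kind, t, end))
            imm_start = None
            prev_kind = kind
            t = end
            continue
        prev_kind = "Q"

        # quiescence bout under the closed-loop monitor
        clock = imm_start if imm_start is not None else t
        seg = t
        interrupted = False
        while True:
            fire = None
            if monitored:
                f = max(clock, w0) + trigger_s
                if f < end and f < w1 and f >= w0:
                    fire = f
            if fire is None:
                if end > seg:
                    segments.append(("Q", seg, end))
                imm_start = clock
                t = end
                break
            if fire > seg:
                segments.append(("Q", seg, fire))
            rotations.append(fire)
            rot_end = min(fire + 1.0, total)
            segments.append(("R", fire, rot_end))
            if rng.random() < config.compliance:
                interrupted = True
                imm_start = None
                t = rot_end
                break
            clock = fire + 1.0
            seg = rot_end
            if seg >= end:
                imm_start = clock
                t = seg
                break
        if interrupted and config.post_rotation_arousal_s > 0 and t < total:
            a_end = min(t + config.post_rotation_arousal_s, total)
            segments.append(("W", t, a_end))
            prev_kind = "W"
            t = a_end
    return segments, rotations, indiv


_PRIORITY = {"Q": 0, "M": 1, "W": 2, "R": 3}


def _rasterize(segments, config, rng) -> TrackingSeries:
    eps = config.epoch_s
    total = config.duration_h * 3600.0
    n = int(round(total / eps))
    L = config.tube_length_mm
    kind_ep = np.zeros(n, dtype=np.int8)
    x_ep = np.full(n, np.nan)
    p_food = config.resolved_food_attraction()

    cur_x = float(rng.uniform(5.0, L - 5.0))
    for kind, t0, t1 in segments:
        i0 = max(int(math.floor(t0 / eps)), 0)
        i1 = min(int(math.ceil(t1 / eps)), n)
        if i1 <= i0:
            continue
        pri = _PRIORITY[kind]
        np.maximum(kind_ep[i0:i1], pri, out=kind_ep[i0:i1])
        m = i1 - i0
        if kind in ("Q", "R"):
            x_ep[i0:i1] = cur_x
        elif kind == "M":
            if rng.random() < p_food:
                cur_x = float(rng.uniform(0.0, 4.0))
            x_ep[i0:i1] = np.clip(cur_x + rng.uniform(-1.0, 1.0, m), 0.0, L)
        else:  # walking: tube-spanning zigzag, crosses the midline every epoch
            a = float(rng.uniform(3.0, 12.0))
            b = float(rng.uniform(L - 12.0, L - 3.0))
            pts = np.where(np.arange(m) % 2 == 0, a, b)
            x_ep[i0:i1] = np.clip(pts + rng.uniform(-1.0, 1.0, m), 0.0, L)
            cur_x = float(x_ep[i1 - 1])

    # fill any float-gap epochs by carrying the last position forward
    nan = np.isnan(x_ep)
    if nan.any():
        idx = np.where(~nan, np.arange(n), 0)
        np.maximum.accumulate(idx, out=idx)
        x_ep = x_ep[idx]
        x_ep[np.isnan(x_ep)] = cur_x

    v = rng.uniform(0.0, 0.45, n)
    for code, lo, hi in ((1, 1.5, 3.0), (2, 8.0, 20.0), (3, 40.0, 60.0)):
        sel = kind_ep == code
        k = int(sel.sum())
        if k:
            v[sel] = rng.uniform(lo, hi, k)

    return TrackingSeries(
        animal_id=f"sim{config.seed}",
        t=np.arange(n) * eps,
        x=x_ep,
        v_max=v,
        epoch_s=eps,
        tube_length_mm=L,
    )


def simulate_deprivation(
    config: SimConfig,
    trigger_s: float,
    window: tuple[float, float] | None = None,
    return_segments: bool = False,
):
    """Simulate one fly under closed-loop deprivation.

    ``trigger_s = inf`` is the undisturbed sentinel: the stimulus log is
    empty and the trace is identical to :func:`simulate_fly` at the same
    seed.  ``window`` restricts the monitor to an absolute time interval
    (seconds); outside it the device is off.
    """
    config.validate()
    if np.isfinite(trigger_s) and trigger_s <= config.epoch_s:
        raise ConfigError(
            f"trigger_s: {trigger_s} s is unresolvable at {config.epoch_s}-s epochs"
        )
    rng = np.random.default_rng(config.seed)
    segments, rotations, _ = _draw_bouts(config, rng, trigger_s, window)
    series = _rasterize(segments, config, rng)
    log = StimulusLog(
        animal_id=series.animal_id,
        t_onset=np.asarray(rotations, dtype=float),
        duration=np.full(len(rotations), 1.0),
    )
    if return_segments:
        return series, log, segments
    return series, log


def simulate_fly(config: SimConfig) -> TrackingSeries:
    """Simulate one undisturbed fly."""
    series, _ = simulate_deprivation(config, math.inf)
    return series


# ---------------------------------------------------------------------------
# calibration: expected scored sleep from the generative parameters
# ---------------------------------------------------------------------------

def expected_scored_sleep_fraction(
    config: SimConfig, quiescence_rate: float | None = None, min_bout_s: float = 300.0
) -> float:
    """Analytic expectation of the pipeline-scored sleep fraction.

    The alternating process is a renewal cycle of one quiescence bout
    followed by 1 + Geometric active bouts; occupancy is evaluated on a
    fine circadian-phase grid, with the lognormal partial expectation for
    the >300 s rule and an epoch-quantisation loss of one epoch per bout.
    """
    rates = config.resolved_rates()
    durs = config.resolved_durations()
    wq = rates["quiescence"] if quiescence_rate is None else quiescence_rate
    muq, sq = durs["quiescence"]
    e_q = math.exp(muq + sq * sq / 2.0)
    c = min_bout_s + config.epoch_s / 2.0
    if sq > 0:
        p_gt = 1.0 - norm.cdf((math.log(c) - muq) / sq)
        e_trunc = e_q * norm.cdf((muq + sq * sq - math.log(c)) / sq)
    else:
        p_gt = 1.0 if math.exp(muq) > c else 0.0
        e_trunc = e_q * p_gt
    eff = max(e_trunc - config.epoch_s * p_gt, 0.0)

    def mean_active(state):
        mu, sg = durs[state]
        return math.exp(mu + sg * sg / 2.0)

    wa0 = rates["micromovement"] + rates["walking"]
    if wa0 <= 0:
        return eff / e_q
    # mean active-bout duration; the circadian gain cancels in the type mix
    a_bar = (
        rates["micromovement"] * mean_active("micromovement")
        + rates["walking"] * mean_active("walking")
    ) / wa0
    grid = np.linspace(0.0, 24.0, 481)[:-1]
    g = circadian_gain(grid, config.circadian_amplitude)
    # gain multiplies active weights and divides the quiescence weight
    cycle = e_q + (1.0 + g * wa0 / (wq / g)) * a_bar  # one Q + 1+Geometric active
    return float(np.mean(eff / cycle))


def calibrate_quiescence_rate(
    target_fraction: float, config: SimConfig, min_bout_s: float = 300.0
) -> SimConfig:
    """Return a config whose quiescence weight targets a scored sleep fraction."""
    if not 0.0 < target_fraction < 1.0:
        raise ConfigError("target_fraction: must be in (0, 1)")
    sup = expected_scored_sleep_fraction(config, quiescence_rate=1e12, min_bout_s=min_bout_s)
    if target_fraction >= sup:
        raise ConfigError(
            f"target_fraction: {target_fraction} unreachable (max ~{sup:.3f} "
            "given the bout-duration parameters)"
        )
    f = lambda w: expected_scored_sleep_fraction(config, w, min_bout_s) - target_fraction
    wq = brentq(f, 1e-9, 1e12)
    rates = dict(config.state_rates or _default_rates(config.sex))
    rates["quiescence"] = wq
    return replace(config, state_rates=rates)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def simulate_cohort(
    n: int,
    config: SimConfig,
    lifespan: LifespanConfig | None = None,
    t_v: float = 1.0,
    t_d: float = 15.0,
) -> pd.DataFrame:
    """Simulate and score ``n`` independent flies; returns a cohort table.

    Per-fly seeds derive from the master seed by ``SeedSequence.spawn``.
    Lifespans are Weibull draws (sex-specific) shifted by
    ``sleep_effect x scored sleep (h/day)``; censored rows carry the
    censoring time in ``lifespan_days``.
    """
    from .ethogram import score_ethogram, summarize  # local import: avoid cycle

    if n < 1:
        raise ConfigError("n: must be >= 1")
    config.validate()
    lifespan = (lifespan or LifespanConfig()).validate()
    if config.duration_h < 24:
        raise ConfigError("duration_h: cohort scoring needs at least one full day")

    children = np.random.SeedSequence(config.seed).spawn(n)
    rows = []
    for i, child in enumerate(children):
        sim_ss, life_ss = child.spawn(2)
        fly_seed = int(sim_ss.generate_state(1)[0] % (2**31))
        series = simulate_fly(replace(config, seed=fly_seed))
        eth = score_ethogram(series, t_v=t_v, t_d=t_d, lights_on_s=config.lights_on_s)
        summ = summarize(eth)
        sleep_h = summ.sleep_min_per_day / 60.0

        rng = np.random.default_rng(life_ss)
        sex = config.sex
        life = float(
            lifespan.scale_days[sex] * rng.weibull(lifespan.shape[sex])
            + lifespan.sleep_effect * sleep_h
        )
        life = max(life, 0.1)
        censored = bool(rng.random() < lifespan.censor_rate)
        if censored:
            life *= float(rng.uniform(0.3, 0.9))
        rows.append(
            {
                "animal_id": f"fly{i:04d}",
                "sex": sex,
                "treatment": "control",
                "sleep_min_per_day": summ.sleep_min_per_day,
                "sleep_h_per_day": sleep_h,
                "micromovement_min_per_day": summ.micromovement_min_per_day,
                "lifespan_days": life,
                "censored": censored,
            }
        )
    return pd.DataFrame(rows)
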