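"""Immobility, sleep and behavioral-state scoring of tracking series.

The scoring chain is:

1. :func:`score_immobility` — an epoch is immobile when its maximal velocity
   is strictly below the threshold ``t_v`` (mm/s).
2. :func:`mask_stimuli` — epochs overlapping the 6 s after each tube
   rotation are masked: the spin itself registers as spurious velocity, so
   masked epochs are excluded from sleep scoring without breaking an
   immobility run.
3. :func:`annotate_sleep` — the 5-minute rule: any immobility run strictly
   longer than 300 s is a sleep bout, counted in full (including its first
   300 s).
4. :func:`classify_minutes` — each complete minute is labelled quiescence
   (every epoch immobile), micromovement (mobile but total displacement
   below ``t_d`` = 15 mm) or walking (the remainder).

``t_v`` has no universal value — it is a property of the upstream tracker's
velocity calibration — so it defaults to 1 mm/s and is exposed everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import StimulusLog, TrackingSeries, day_index, zt

__all__ = [
    "QUIESCENCE",
    "MICROMOVEMENT",
    "WALKING",
    "STATE_NAMES",
    "Ethogram",
    "SleepSummary",
    "score_immobility",
    "mask_stimuli",
    "annotate_sleep",
    "classify_minutes",
    "normalize_position",
    "vdam_rescore",
    "score_ethogram",
    "summarize",
    "window_sleep_min",
]

QUIESCENCE, MICROMOVEMENT, WALKING = 0, 1, 2
STATE_NAMES = ("quiescence", "micromovement", "walking")


def score_immobility(series: TrackingSeries, t_v: float = 1.0) -> np.ndarray:
    """Epoch-level immobility flags: ``v_max < t_v`` (strict inequality)."""
    if t_v <= 0:
        raise ValueError("t_v must be positive")
    return series.v_max < t_v


def mask_stimuli(
    series: TrackingSeries,
    stim: StimulusLog | None,
    mask_s: float = 6.0,
) -> np.ndarray:
    """Flag epochs overlapping ``[t_onset, t_onset + mask_s)`` of any rotation."""
    if mask_s < 0:
        raise ValueError("mask_s must be >= 0")
    n = len(series)
    masked = np.zeros(n, dtype=bool)
    if stim is None or len(stim) == 0 or mask_s == 0:
        return masked
    eps = series.epoch_s
    t0 = series.t[0]
    span_end = series.t[-1] + eps
    outside = (stim.t_onset < t0) | (stim.t_onset >= span_end)
    if np.any(outside):
        warnings.warn(
            f"{series.animal_id}: {int(outside.sum())} stimulus onset(s) outside the "
            "recording span",
            stacklevel=2,
        )
    i0 = np.floor((stim.t_onset - t0) / eps).astype(int)
    i1 = np.ceil((stim.t_onset + mask_s - t0) / eps).astype(int)
    for a, b in zip(np.clip(i0, 0, n), np.clip(i1, 0, n)):
        masked[a:b] = True
    return masked


def annotate_sleep(
    immobile: np.ndarray,
    masked: np.ndarray | None = None,
    epoch_s: float = 10.0,
    min_bout_s: float = 300.0,
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Apply the 5-minute rule to epoch flags.

    Masked epochs are neutral: they neither count as mobility (they do not
    break a run) nor start or end one.  A candidate run is a maximal stretch
    of immobile-or-masked epochs trimmed to its first and last genuinely
    immobile epoch; its duration is the trimmed span.  Runs strictly longer
    than ``min_bout_s`` become sleep bouts and are asleep in full,
    including interior masked epochs.

    Returns ``(asleep flags, bouts)`` with bouts as ``(start_s, end_s)``
    half-open intervals relative to the flag grid.
    """
    immobile = np.asarray(immobile, dtype=bool)
    n = len(immobile)
    if masked is None:
        masked = np.zeros(n, dtype=bool)
    masked = np.asarray(masked, dtype=bool)
    eligible = immobile | masked
    asleep = np.zeros(n, dtype=bool)
    bouts: list[tuple[float, float]] = []

    # maximal runs of eligible epochs
    padded = np.concatenate(([False], eligible, [False]))
    starts = np.flatnonzero(padded[1:] & ~padded[:-1])
    ends = np.flatnonzero(~padded[1:] & padded[:-1])  # exclusive
    truly = immobile & ~masked
    for a, b in zip(starts, ends):
        idx = np.flatnonzero(truly[a:b])
        if idx.size == 0:
            continue  # masked-only stretch: nothing to score
        i, j = a + idx[0], a + idx[-1] + 1  # trimmed, half-open
        if (j - i) * epoch_s > min_bout_s:
            asleep[i:j] = True
            bouts.append((i * epoch_s, j * epoch_s))
    return asleep, bouts


def classify_minutes(
    series: TrackingSeries,
    t_v: float = 1.0,
    t_d: float = 15.0,
    immobile: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Label each complete minute quiescence / micromovement / walking.

    A minute is quiescence when every epoch is immobile; otherwise
    micromovement when the summed epoch-to-epoch displacement within the
    minute is below ``t_d`` mm, walking when it reaches it.  The minute grid
    is anchored at the recording start and the incomplete trailing minute is
    dropped.  Returns ``(states, per-minute distance in mm)``.
    """
    epm = int(round(60.0 / series.epoch_s))
    n_min = len(series) // epm
    if n_min < 1:
        raise ValueError("need at least one complete minute")
    if immobile is None:
        immobile = score_immobility(series, t_v)
    imm = immobile[: n_min * epm].reshape(n_min, epm)
    x = series.x[: n_min * epm].reshape(n_min, epm)
    dist = np.abs(np.diff(x, axis=1)).sum(axis=1)
    states = np.where(
        imm.all(axis=1), QUIESCENCE, np.where(dist < t_d, MICROMOVEMENT, WALKING)
    )
    return states, dist


def normalize_position(series: TrackingSeries) -> np.ndarray:
    """Express position relative to the occupied range.

    ``(x - Q01(x)) / Q99(x - Q01(x))`` with quantiles over the whole
    recording, so the food end maps near 0 and the cotton end near 1; the
    extreme percentiles may fall slightly outside [0, 1] by construction.
    """
    x = series.x
    if len(x) < 100:
        raise ValueError("need >= 100 epochs for stable percentiles")
    q01 = np.quantile(x, 0.01)
    shifted = x - q01
    denom = np.quantile(shifted, 0.99)
    if denom <= 0:
        raise ValueError("degenerate positional range")
    return shifted / denom


def vdam_rescore(
    series: TrackingSeries, min_bout_s: float = 300.0
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Re-score sleep as a virtual beam-crossing activity monitor would.

    Activity is a midline crossing (the sign of ``x - tube_length/2``
    changing between consecutive epochs); every crossing-free interval
    longer than ``min_bout_s`` counts as sleep in full.  Because in-place
    micromovement never crosses the midline, this systematically
    overestimates sleep relative to velocity-based scoring.
    """
    mid = series.tube_length_mm / 2.0
    side = series.x >= mid
    n = len(side)
    cross = np.flatnonzero(side[1:] != side[:-1]) + 1  # crossing enters epoch i
    bounds = np.concatenate(([0], cross, [n]))
    asleep = np.zeros(n, dtype=bool)
    bouts: list[tuple[float, float]] = []
    eps = series.epoch_s
    for a, b in zip(bounds[:-1], bounds[1:]):
        if (b - a) * eps > min_bout_s:
            asleep[a:b] = True
            bouts.append((a * eps, b * eps))
    return asleep, bouts


@dataclass
class Ethogram:
    """Scored behavior of one animal: epoch flags plus minute states."""

    animal_id: str
    epoch_s: float
    t: np.ndarray  # epoch start times, s
    immobile: np.ndarray
    masked: np.ndarray
    asleep: np.ndarray
    sleep_bouts: list[tuple[float, float]]
    minute_states: np.ndarray  # 0/1/2 per complete minute
    minute_distance_mm: np.ndarray
    lights_on_s: float = 0.0

    @property
    def minute_t(self) -> np.ndarray:
        return np.arange(len(self.minute_states)) * 60.0 + self.t[0]

    def sleep_min_total(self) -> float:
        return float(self.asleep.sum()) * self.epoch_s / 60.0


def score_ethogram(
    series: TrackingSeries,
    stim: StimulusLog | None = None,
    t_v: float = 1.0,
    t_d: float = 15.0,
    min_bout_s: float = 300.0,
    mask_s: float = 6.0,
    lights_on_s: float = 0.0,
) -> Ethogram:
    """Full scoring chain for one animal."""
    immobile = score_immobility(series, t_v)
    masked = mask_stimuli(series, stim, mask_s)
    asleep, bouts = annotate_sleep(immobile, masked, series.epoch_s, min_bout_s)
    states, dist = classify_minutes(series, t_v, t_d, immobile=immobile)
    return Ethogram(
        animal_id=series.animal_id,
        epoch_s=series.epoch_s,
        t=series.t,
        immobile=immobile,
        masked=masked,
        asleep=asleep,
        sleep_bouts=bouts,
        minute_states=states,
        minute_distance_mm=dist,
        lights_on_s=lights_on_s,
    )


def window_sleep_min(
    eth: Ethogram, zt_window: tuple[float, float], day: int
) -> float | None:
    """Minutes asleep inside ``[zt_lo, zt_hi)`` hours of experimental ``day``.

    Returns None when the window is not fully covered by the recording.
    """
    lo, hi = zt_window
    t0 = eth.lights_on_s + day * 86400.0 + lo * 3600.0
    t1 = eth.lights_on_s + day * 86400.0 + hi * 3600.0
    sel = (eth.t >= t0) & (eth.t < t1)
    expected = int(round((t1 - t0) / eth.epoch_s))
    if sel.sum() < expected:
        return None
    return float(eth.asleep[sel].sum()) * eth.epoch_s / 60.0


@dataclass
class SleepSummary:
    animal_id: str
    n_days: int
    sleep_min_per_day: float
    profile_30min: np.ndarray = field(repr=False)  # 48-bin fraction asleep
    micromovement_min_per_day: float = 0.0
    walking_min_per_day: float = 0.0
    walked_distance_mm_per_day: float = 0.0
    mean_position: float = np.nan
    position_profile_30min: np.ndarray | None = field(default=None, repr=False)


def summarize(eth: Ethogram, series: TrackingSeries | None = None) -> SleepSummary:
    """Daily averages and 48-bin ZT profiles over the complete days.

    A day is complete when all its epochs (ZT0 to ZT24) lie inside the
    recording.  Position summaries need the original series and are skipped
    otherwise.
    """
    eps = eth.epoch_s
    days = day_index(eth.t, eth.lights_on_s)
    per_day = int(round(86400.0 / eps))
    counts = np.bincount(days - days.min())
    full = np.flatnonzero(counts == per_day) + days.min()
    if full.size == 0:
        raise ValueError("no complete ZT day in recording")
    in_full = np.isin(days, full)
    n_days = int(full.size)

    sleep_min = float(eth.asleep[in_full].sum()) * eps / 60.0 / n_days

    bins = np.floor(zt(eth.t, eth.lights_on_s) * 2).astype(int)  # 30-min bins
    profile = np.zeros(48)
    for b in range(48):
        sel = in_full & (bins == b)
        profile[b] = eth.asleep[sel].mean() if sel.any() else 0.0

    mdays = day_index(eth.minute_t, eth.lights_on_s)
    m_in = np.isin(mdays, full)
    mm_min = float((eth.minute_states[m_in] == MICROMOVEMENT).sum()) / n_days
    walk_min = float((eth.minute_states[m_in] == WALKING).sum()) / n_days
    walked = float(
        eth.minute_distance_mm[m_in & (eth.minute_states == WALKING)].sum()
    ) / n_days

    mean_pos = np.nan
    pos_profile = None
    if series is not None:
        pos = normalize_position(series)
        mean_pos = float(pos[in_full].mean())
        pos_profile = np.array(
            [pos[in_full & (bins == b)].mean() if (in_full & (bins == b)).any() else np.nan
             for b in range(48)]
        )
    return SleepSummary(
        animal_id=eth.animal_id,
        n_days=n_days,
        sleep_min_per_day=sleep_min,
        profile_30min=profile,
        micromovement_min_per_day=mm_min,
        walking_min_per_day=walk_min,
        walked_distance_mm_per_day=walked,
        mean_position=mean_pos,
        position_profile_30min=pos_profile,
    )
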