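"""Circadian variance decomposition of stimulus-count time series.

Under chronic closed-loop deprivation every tube rotation marks a moment the
animal tried to sleep, so the rotation count per time bin is a proxy for
instantaneous sleep pressure.  The binned series is split additively into

    observed = trend + periodic + residual

by classical seasonal decomposition: the trend is a centered moving average
over one period (24 h), the periodic component is the per-phase mean of the
detrended series re-centered to zero, and the residual is the remainder.
The share of sleep pressure governed by the clock versus the cumulative
deprivation history is then reported as component variance over observed
variance on the support where the trend is defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.tsa.seasonal import seasonal_decompose as _sm_decompose

from .io import StimulusLog

__all__ = ["rotation_counts", "seasonal_decompose", "DecompositionResult"]


def rotation_counts(
    stim,
    bin_h: float = 0.5,
    lights_on_s: float = 0.0,
    t_span: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram rotation onsets on ZT-aligned half-open bins, zero-filled.

    ``stim`` is a :class:`~ethosleep.io.StimulusLog` or a raw array of onset
    times (e.g. events pooled over a cohort, where exact ties are allowed).
    ``bin_h`` must divide 24 so the bins tile whole circadian days.
    Returns ``(bin start times s, counts)``.
    """
    if bin_h <= 0 or abs(24.0 / bin_h - round(24.0 / bin_h)) > 1e-9:
        raise ValueError("bin_h must be a positive divisor of 24")
    onsets = stim.t_onset if isinstance(stim, StimulusLog) else np.asarray(stim, float)
    w = bin_h * 3600.0
    if t_span is None:
        hi = float(onsets.max()) + 1.0 if len(onsets) else w
        t_span = (0.0, hi)
    lo_s, hi_s = t_span
    # align the grid so bin boundaries sit on the ZT lattice
    start = lights_on_s + np.floor((lo_s - lights_on_s) / w) * w
    n_bins = int(np.ceil((hi_s - start) / w))
    edges = start + np.arange(n_bins + 1) * w
    counts, _ = np.histogram(onsets, bins=edges)
    return edges[:-1], counts.astype(float)


@dataclass
class DecompositionResult:
    bin_h: float
    observed: np.ndarray = field(repr=False)
    trend: np.ndarray = field(repr=False)
    periodic: np.ndarray = field(repr=False)
    residual: np.ndarray = field(repr=False)
    f_periodic: float = 0.0
    f_trend: float = 0.0
    f_residual: float = 0.0
    degenerate: bool = False

    def summary(self) -> str:
        lines = [
            "Seasonal decomposition of rotation counts",
            "=" * 41,
            f"bins                : {len(self.observed)} x {self.bin_h} h",
            f"variance, periodic  : {self.f_periodic:6.1%}",
            f"variance, trend     : {self.f_trend:6.1%}",
            f"variance, residual  : {self.f_residual:6.1%}",
        ]
        if self.degenerate:
            lines.append("series is constant: fractions defined as 0 (degenerate)")
        return "\n".join(lines)


def seasonal_decompose(
    series, period_bins: int, bin_h: float = 0.5
) -> DecompositionResult:
    """Additive circadian/trend/residual split with variance fractions.

    ``period_bins`` is the number of bins per 24-h period; the series must
    cover at least two periods.  Fractions are Var(component)/Var(observed)
    on the trimmed support (trend undefined at the half-period edges).
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 2 * period_bins:
        raise ValueError("series must span at least two periods")
    total_var = float(np.var(x))
    if total_var <= 0:
        z = np.zeros_like(x)
        return DecompositionResult(
            bin_h=bin_h, observed=x, trend=x.copy(), periodic=z, residual=z,
            degenerate=True,
        )
    res = _sm_decompose(x, period=period_bins, model="additive", two_sided=True)
    ok = ~np.isnan(res.trend)
    obs, tr = x[ok], res.trend[ok]
    per, rem = res.seasonal[ok], res.resid[ok]
    v_obs = float(np.var(obs))
    return DecompositionResult(
        bin_h=bin_h,
        observed=x,
        trend=res.trend,
        periodic=res.seasonal,
        residual=res.resid,
        f_periodic=float(np.var(per) / v_obs),
        f_trend=float(np.var(tr) / v_obs),
        f_residual=float(np.var(rem) / v_obs),
    )
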