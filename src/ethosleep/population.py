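"""Cohort-level statistics: basic bootstrap, Kaplan-Meier survival with a
censoring-aware median CI, and the lifespan ~ sleep x sex regression.

Inference throughout is estimation-based (confidence intervals, no
p-values).  The bootstrap is the *basic* (reflected) form: with point
estimate t and bootstrap quantiles q, the interval is
``(2t - q_hi, 2t - q_lo)``.  The survival machinery delegates to lifelines:
the product-limit estimator with Greenwood variance on the log(-log) scale,
whose intersection with 0.5 yields the Brookmeyer-Crowley style median CI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from lifelines import KaplanMeierFitter
from lifelines.utils import median_survival_times

__all__ = [
    "bootstrap_ci",
    "km_fit",
    "SurvivalFit",
    "LifespanSleepModel",
    "LifespanRegressionResults",
    "lifespan_regression",
]


def bootstrap_ci(
    values,
    statistic=np.mean,
    n_boot: int = 1000,
    level: float = 0.95,
    seed=None,
) -> tuple[float, float, float]:
    """Basic-bootstrap confidence interval: ``(estimate, lo, hi)``."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need >= 2 values")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; CI will be unstable", stacklevel=2)
    rng = np.random.default_rng(seed)
    est = float(statistic(x))
    if statistic is np.mean:  # vectorised fast path
        idx = rng.integers(0, len(x), size=(n_boot, len(x)))
        boots = x[idx].mean(axis=1)
    else:
        boots = np.array(
            [statistic(x[rng.integers(0, len(x), len(x))]) for _ in range(n_boot)]
        )
    a = (1.0 - level) / 2.0
    q_lo, q_hi = np.quantile(boots, [a, 1.0 - a])
    return est, 2.0 * est - float(q_hi), 2.0 * est - float(q_lo)


@dataclass
class SurvivalFit:
    """Product-limit survival curve with censoring-aware median CI."""

    label: str
    timeline: np.ndarray = field(repr=False)
    survival: np.ndarray = field(repr=False)
    ci_lower: np.ndarray = field(repr=False)
    ci_upper: np.ndarray = field(repr=False)
    median: float = np.nan
    median_ci: tuple[float, float] = (np.nan, np.nan)
    n: int = 0
    n_events: int = 0
    all_censored: bool = False

    def survival_at(self, t) -> np.ndarray:
        """Step-function evaluation S(t)."""
        idx = np.searchsorted(self.timeline, np.atleast_1d(t), side="right") - 1
        return self.survival[np.clip(idx, 0, len(self.survival) - 1)]

    def summary(self) -> str:
        lo, hi = self.median_ci
        return "\n".join(
            [
                f"Kaplan-Meier fit: {self.label or '(unnamed)'}",
                f"subjects {self.n}, events {self.n_events}",
                f"median survival: {self.median:g} (95% CI [{lo:g}, {hi:g}])",
            ]
        )


def km_fit(durations, event_observed=None, label: str = "") -> SurvivalFit:
    """Kaplan-Meier estimate; ``event_observed`` False marks right-censoring."""
    durations = np.asarray(durations, dtype=float)
    if event_observed is None:
        event_observed = np.ones(len(durations), dtype=bool)
    event_observed = np.asarray(event_observed, dtype=bool)
    if len(durations) == 0:
        raise ValueError("empty sample")
    all_censored = not event_observed.any()
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=event_observed, label=label or "KM")
    ci = kmf.confidence_interval_
    if all_censored:
        median, med_ci = np.nan, (np.nan, np.nan)
        warnings.warn("all observations censored: median undefined", stacklevel=2)
    else:
        median = float(kmf.median_survival_time_)
        med = median_survival_times(ci)
        med_ci = (float(med.iloc[0, 0]), float(med.iloc[0, 1]))
    return SurvivalFit(
        label=label,
        timeline=kmf.survival_function_.index.to_numpy(dtype=float),
        survival=kmf.survival_function_.iloc[:, 0].to_numpy(),
        ci_lower=ci.iloc[:, 0].to_numpy(),
        ci_upper=ci.iloc[:, 1].to_numpy(),
        median=median,
        median_ci=med_ci,
        n=len(durations),
        n_events=int(event_observed.sum()),
        all_censored=all_censored,
    )


# ---------------------------------------------------------------------------
# lifespan ~ sleep x sex
# ---------------------------------------------------------------------------

def _sex_slope(sleep: np.ndarray, life: np.ndarray) -> float:
    var = np.mean((sleep - sleep.mean()) ** 2)
    return float(np.mean((life - life.mean()) * (sleep - sleep.mean())) / var)


class LifespanSleepModel:
    """OLS of lifespan on daily sleep with a full sleep x sex interaction.

    Inclusion filters applied on construction (and audited): untreated
    animals only, lifespan of at least ``min_lifespan_days`` (removes the
    moribund period), right-censored animals excluded.  The cohort table
    must carry ``sleep_h_per_day`` already averaged over the first days of
    recording.
    """

    def __init__(self, cohort: pd.DataFrame, min_lifespan_days: float = 20.0):
        df = cohort.copy()
        audit = {"input": len(df)}
        if "treatment" in df.columns:
            df = df[df["treatment"] == "control"]
        audit["removed_treated"] = audit["input"] - len(df)
        n0 = len(df)
        if "censored" in df.columns:
            df = df[~df["censored"].astype(bool)]
        audit["removed_censored"] = n0 - len(df)
        n0 = len(df)
        df = df[df["lifespan_days"] >= min_lifespan_days]
        audit["removed_short_lived"] = n0 - len(df)
        audit["analyzed"] = len(df)
        self.data = df.reset_index(drop=True)
        self.filter_audit = audit

    def fit(self, n_boot: int = 1000, level: float = 0.95, seed=None):
        df = self.data
        rng = np.random.default_rng(seed)
        ols = smf.ols("lifespan_days ~ sleep_h_per_day * C(sex)", data=df).fit()

        slopes: dict[str, tuple[float, float, float] | None] = {}
        for sex in sorted(df["sex"].unique()):
            sub = df[df["sex"] == sex]
            if len(sub) < 4 or sub["sleep_h_per_day"].var() == 0:
                slopes[sex] = None
                continue
            sleep = sub["sleep_h_per_day"].to_numpy()
            life = sub["lifespan_days"].to_numpy()
            est = _sex_slope(sleep, life)
            # basic bootstrap over animals within the sex
            n = len(sub)
            idx = rng.integers(0, n, size=(n_boot, n))
            s_b = sleep[idx]
            l_b = life[idx]
            s_c = s_b - s_b.mean(axis=1, keepdims=True)
            l_c = l_b - l_b.mean(axis=1, keepdims=True)
            boots = (s_c * l_c).mean(axis=1) / (s_c**2).mean(axis=1)
            a = (1.0 - level) / 2.0
            q_lo, q_hi = np.quantile(boots, [a, 1.0 - a])
            slopes[sex] = (est, 2 * est - float(q_hi), 2 * est - float(q_lo))
        return LifespanRegressionResults(
            params=ols.params.to_dict(),
            r_squared=float(ols.rsquared),
            slopes=slopes,
            level=level,
            filter_audit=dict(self.filter_audit),
            n=len(df),
            ols=ols,
        )


@dataclass
class LifespanRegressionResults:
    params: dict
    r_squared: float
    slopes: dict  # sex -> (estimate, lo, hi) in days of life per hour of sleep
    level: float
    filter_audit: dict
    n: int
    ols: object = field(repr=False, default=None)

    def summary(self) -> str:
        lines = [
            "Lifespan ~ sleep x sex (OLS, per-sex slopes bootstrapped)",
            "=" * 57,
            f"animals analyzed : {self.n}  (audit: {self.filter_audit})",
            f"R^2              : {self.r_squared:.3f}",
        ]
        for sex, s in self.slopes.items():
            if s is None:
                lines.append(f"{sex:<7}: slope unavailable (insufficient data)")
            else:
                est, lo, hi = s
                lines.append(
                    f"{sex:<7}: {est:+.2f} days of life per hour of sleep "
                    f"({self.level:.0%} CI [{lo:+.2f}, {hi:+.2f}])"
                )
        return "\n".join(lines)


def lifespan_regression(
    cohort: pd.DataFrame,
    min_lifespan_days: float = 20.0,
    n_boot: int = 1000,
    level: float = 0.95,
    seed=None,
) -> LifespanRegressionResults:
    """Convenience wrapper: construct and fit :class:`LifespanSleepModel`."""
    return LifespanSleepModel(cohort, min_lifespan_days).fit(
        n_boot=n_boot, level=level, seed=seed
    )
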