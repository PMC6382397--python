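"""Tabular I/O and time conventions for single-fly tracking data.

Every downstream stage consumes time through :func:`zt` / :func:`day_index`
so that zeitgeber conventions (ZT0 = lights on, half-open bins, day
boundaries at ZT0) are defined in exactly one place.

Canonical interchange formats are plain CSV files with an optional JSON
sidecar carrying recording context (epoch length, tube length), chosen for
inspectability over columnar binary:

* tracking CSV   — ``animal_id,t,x,vmax``; ``t`` in seconds since recording
  start, epoch-aligned; ``x`` in mm from the food end (food = 0).
* stimulus CSV   — ``animal_id,t_onset,duration`` (tube rotations).
* metadata CSV   — one row per animal mirroring :class:`AnimalMetadata`.
* Newick         — serialised UPGMA dendrograms.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "TrackingSeries",
    "AnimalMetadata",
    "StimulusLog",
    "TrackingFormatError",
    "zt",
    "day_index",
    "read_tracking",
    "write_tracking",
    "read_stimuli",
    "write_stimuli",
    "read_metadata",
    "write_metadata",
    "write_newick",
    "read_ethoscope_db",
]


class TrackingFormatError(ValueError):
    """Raised when a tracking table violates the format contract."""


def zt(t, lights_on_s: float = 0.0):
    """Map seconds-since-start to zeitgeber time in hours, in [0, 24)."""
    return ((np.asarray(t, dtype=float) - lights_on_s) / 3600.0) % 24.0


def day_index(t, lights_on_s: float = 0.0):
    """Experimental day number; day boundaries fall at ZT0."""
    return np.floor((np.asarray(t, dtype=float) - lights_on_s) / 86400.0).astype(int)


@dataclass
class TrackingSeries:
    """One animal's epoch-level (t, x, v_max) trace.

    ``t`` must be strictly increasing with uniform spacing ``epoch_s``; ``x``
    is the longitudinal position in mm measured from the food end of the
    tube; ``v_max`` the maximal velocity (mm/s) observed within each epoch.
    """

    animal_id: str
    t: np.ndarray
    x: np.ndarray
    v_max: np.ndarray
    epoch_s: float = 10.0
    tube_length_mm: float = 70.0
    out_of_tube: np.ndarray | None = None  # flag column, never dropped

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.v_max = np.asarray(self.v_max, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.v_max)):
            raise TrackingFormatError(
                f"{self.animal_id}: t/x/vmax length mismatch "
                f"({len(self.t)}/{len(self.x)}/{len(self.v_max)})"
            )

    def __len__(self) -> int:
        return len(self.t)

    def validate(self, position_tol_mm: float = 2.0) -> "TrackingSeries":
        """Enforce the series invariants; flags (not drops) stray positions."""
        dt = np.diff(self.t)
        if np.any(dt == 0):
            i = int(np.argmax(dt == 0))
            raise TrackingFormatError(
                f"duplicated timestamp for animal {self.animal_id} at t={self.t[i]:g}"
            )
        if np.any(dt <= 0):
            raise TrackingFormatError(f"{self.animal_id}: time not strictly increasing")
        if len(dt) and not np.allclose(dt, self.epoch_s, rtol=0, atol=1e-6):
            raise TrackingFormatError(
                f"{self.animal_id}: non-uniform epoch spacing (expected {self.epoch_s} s)"
            )
        if np.any(self.v_max < 0):
            raise TrackingFormatError(f"{self.animal_id}: negative v_max")
        stray = (self.x < -position_tol_mm) | (self.x > self.tube_length_mm + position_tol_mm)
        if np.any(stray):
            warnings.warn(
                f"{self.animal_id}: {int(stray.sum())} position(s) outside the tube; flagged",
                stacklevel=2,
            )
        self.out_of_tube = stray
        return self


@dataclass
class AnimalMetadata:
    animal_id: str
    sex: str = "female"  # {male, female}
    treatment: str = "control"  # {control, sleep_deprived}
    trigger_s: float | None = None
    lights_on_s: float = 0.0
    mated: bool | None = None
    death_t_days: float | None = None
    censored: bool = False
    region_food_mm: float = 0.0
    region_cotton_mm: float = 70.0

    def __post_init__(self):
        if self.death_t_days is not None and self.death_t_days <= 0:
            raise ValueError(f"{self.animal_id}: death_t_days must be positive")


@dataclass
class StimulusLog:
    """Closed-loop tube-rotation events for one animal."""

    animal_id: str
    t_onset: np.ndarray = field(default_factory=lambda: np.empty(0))
    duration: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        self.t_onset = np.asarray(self.t_onset, dtype=float)
        if np.size(self.duration) == 0 and len(self.t_onset):
            self.duration = np.full(len(self.t_onset), 1.0)
        self.duration = np.asarray(self.duration, dtype=float)
        if len(self.t_onset) > 1 and np.any(np.diff(self.t_onset) <= 0):
            raise ValueError(f"{self.animal_id}: stimulus onsets not strictly increasing")

    def __len__(self) -> int:
        return len(self.t_onset)


# ---------------------------------------------------------------------------
# tracking CSV (+ JSON sidecar)
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_tracking(series: Iterable[TrackingSeries], path, sidecar: dict | None = None) -> Path:
    path = Path(path)
    series = list(series)
    frames = [
        pd.DataFrame(
            {"animal_id": s.animal_id, "t": s.t, "x": s.x, "vmax": s.v_max}
        )
        for s in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    meta = {
        "epoch_s": series[0].epoch_s if series else 10.0,
        "tube_length_mm": series[0].tube_length_mm if series else 70.0,
        "columns": ["animal_id", "t", "x", "vmax"],
    }
    if sidecar:
        meta.update(sidecar)
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_tracking(path, epoch_s: float | None = None) -> list[TrackingSeries]:
    """Read a tracking CSV into one validated series per animal.

    ``epoch_s`` is taken from the JSON sidecar when present, from the
    argument otherwise, and as a last resort inferred from the time grid.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    required = {"animal_id", "t", "x", "vmax"}
    if not required.issubset(df.columns):
        raise TrackingFormatError(f"missing columns: {sorted(required - set(df.columns))}")
    tube_length = 70.0
    side = _sidecar_path(path)
    if side.exists():
        meta = json.loads(side.read_text())
        epoch_s = meta.get("epoch_s", epoch_s)
        tube_length = meta.get("tube_length_mm", tube_length)
    out = []
    for animal_id, grp in df.groupby("animal_id", sort=True):
        t = grp["t"].to_numpy(dtype=float)
        eps = epoch_s
        if eps is None:
            if len(t) < 2:
                raise TrackingFormatError(f"{animal_id}: cannot infer epoch_s from one row")
            eps = float(np.median(np.diff(t)))
        s = TrackingSeries(
            animal_id=str(animal_id),
            t=t,
            x=grp["x"].to_numpy(dtype=float),
            v_max=grp["vmax"].to_numpy(dtype=float),
            epoch_s=float(eps),
            tube_length_mm=float(tube_length),
        )
        out.append(s.validate())
    return out


# ---------------------------------------------------------------------------
# stimulus + metadata CSV
# ---------------------------------------------------------------------------

def write_stimuli(logs: Iterable[StimulusLog], path) -> Path:
    path = Path(path)
    rows = []
    for log in logs:
        for onset, dur in zip(log.t_onset, log.duration):
            rows.append((log.animal_id, onset, dur))
    pd.DataFrame(rows, columns=["animal_id", "t_onset", "duration"]).to_csv(path, index=False)
    return path


def read_stimuli(path) -> list[StimulusLog]:
    df = pd.read_csv(Path(path))
    return [
        StimulusLog(
            animal_id=str(aid),
            t_onset=grp["t_onset"].to_numpy(dtype=float),
            duration=grp["duration"].to_numpy(dtype=float),
        )
        for aid, grp in df.groupby("animal_id", sort=True)
    ]


def write_metadata(meta: Iterable[AnimalMetadata], path) -> Path:
    path = Path(path)
    pd.DataFrame([asdict(m) for m in meta]).to_csv(path, index=False)
    return path


def read_metadata(path) -> list[AnimalMetadata]:
    df = pd.read_csv(Path(path))
    out = []
    for _, row in df.iterrows():
        d = row.to_dict()
        for key in ("trigger_s", "death_t_days", "mated"):
            if key in d and pd.isna(d[key]):
                d[key] = None
        if d.get("mated") is not None:
            d["mated"] = bool(d["mated"])
        d["censored"] = bool(d.get("censored", False))
        d["animal_id"] = str(d["animal_id"])
        out.append(AnimalMetadata(**d))
    return out


# ---------------------------------------------------------------------------
# Newick serialisation of UPGMA dendrograms
# ---------------------------------------------------------------------------

def newick_string(dendrogram) -> str:
    """Render a :class:`~ethosleep.fingerprint.Dendrogram` as Newick.

    Branch lengths are differences of UPGMA heights, so two leaves joined at
    distance *d* read ``(a:d/2,b:d/2);``.
    """
    labels = list(dendrogram.labels)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate leaf names")
    if len(labels) == 1:
        return f"{labels[0]}:0;"

    heights = {i: 0.0 for i in range(len(labels))}
    rendered = {i: labels[i] for i in range(len(labels))}
    node_id = len(labels)
    for a, b, h, _size in dendrogram.merges:
        la, lb = rendered.pop(a), rendered.pop(b)
        ba, bb = h - heights[a], h - heights[b]
        rendered[node_id] = f"({la}:{ba:.10g},{lb}:{bb:.10g})"
        heights[node_id] = h
        node_id += 1
    (root,) = rendered.values()
    return root + ";"


def write_newick(dendrogram, path) -> Path:
    path = Path(path)
    path.write_text(newick_string(dendrogram) + "\n")
    return path


def read_ethoscope_db(path):
    """Converter stub for the native ethoscope SQLite dialect (out of scope)."""
    raise NotImplementedError(
        "unsupported dialect: native ethoscope SQLite databases are not handled; "
        "export to the tracking CSV format instead"
    )
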