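"""Time-depth record handling: reading, regularization and dive segmentation.

Archival time-depth recorders sample depth every 4 or 10 s.  Before
simulation a record is regularized to 1 Hz by linear interpolation and a
fixed 2 m offset is subtracted (clipping at 0) so that every breathing
event registers as depth 0 - tethered tags and 1 m depth resolution
otherwise leave many surfacings at small positive depths.  A dive is
then simply a maximal run of samples with depth > 0; no minimum-depth
threshold is applied, because gas-embolism risk changes fastest close to
the surface.

Dives are binned by maximum depth into shallow (< 30 m), medium
(30-90 m, boundaries inclusive) and deep (> 90 m) classes, and per-bin
summaries (duration and maximum depth, mean +/- sample SD, proportion of
dives) mirror the published per-animal tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .parameters import Species

__all__ = [
    "RawRecord",
    "DepthSeries",
    "Dive",
    "BINS",
    "read_tdr",
    "regularize",
    "segment_dives",
    "bin_dive",
    "summarize",
    "dive_table",
]

BINS = ("shallow", "medium", "deep")

SHALLOW_MAX = 30.0   # shallow: max depth strictly below this
MEDIUM_MAX = 90.0    # medium: up to and including this; deep beyond


@dataclass(frozen=True)
class RawRecord:
    """A validated, still-irregular time-depth record."""

    times: np.ndarray        # seconds since record start, strictly increasing
    depths: np.ndarray       # metres, >= 0
    sampling_interval: float
    species: Species
    body_mass: float
    id: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        depths = np.asarray(self.depths, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "depths", depths)
        if times.shape != depths.shape or times.ndim != 1:
            raise ValueError("times and depths must be 1-D arrays of equal length")
        dt = np.diff(times)
        if np.any(dt <= 0):
            row = int(np.argmax(dt <= 0)) + 1
            raise ValueError(f"non-monotone time at row {row}: {times[row]}")
        if not np.all(np.isfinite(depths)):
            row = int(np.argmax(~np.isfinite(depths)))
            raise ValueError(f"non-finite depth at row {row}")
        if np.any(depths < 0):
            row = int(np.argmax(depths < 0))
            raise ValueError(f"negative depth at row {row}: {depths[row]}")
        if self.body_mass <= 0:
            raise ValueError("body_mass must be positive")


@dataclass(frozen=True)
class DepthSeries:
    """A 1 Hz depth trace (metres, >= 0; depth 0 means breathing)."""

    depths: np.ndarray
    offset_applied: float = 0.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        d = np.asarray(self.depths, dtype=float)
        object.__setattr__(self, "depths", d)
        if d.ndim != 1:
            raise ValueError("depths must be 1-D")
        if np.any(d < 0) or not np.all(np.isfinite(d)):
            raise ValueError("depths must be finite and >= 0")

    def __len__(self) -> int:
        return self.depths.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.depths.size, dtype=float)


@dataclass(frozen=True)
class Dive:
    """One submergence: a maximal run of samples with depth > 0.

    ``start_index``/``end_index`` are 0-based half-open 1 Hz sample
    indices into the parent series; ``truncated`` flags dives cut off by
    a record boundary (these are excluded from end-dive metrics).
    """

    start_index: int
    end_index: int
    max_depth: float
    mean_depth: float
    truncated: bool = False
    bin: str = field(init=False)

    def __post_init__(self) -> None:
        if self.end_index - self.start_index < 1:
            raise ValueError("a dive spans at least one sample")
        object.__setattr__(self, "bin", bin_dive(self.max_depth))

    @property
    def duration(self) -> float:
        """Seconds submerged (1 Hz samples in the run)."""
        return float(self.end_index - self.start_index)


def read_tdr(path, *, species: Species | str | None = None,
             body_mass: float | None = None, id: str = "") -> RawRecord:
    """Read a two-column TDR CSV (``time_s, depth_m``; header required).

    Animal metadata comes from keyword arguments or, if omitted, from a
    JSON sidecar ``<path>.meta.json`` with keys ``species``, ``body_mass``
    and optionally ``id``.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    for col in ("time_s", "depth_m"):
        if col not in frame.columns:
            raise ValueError(f"{path.name}: missing required column {col!r}")
    if frame["time_s"].isna().any() or frame["depth_m"].isna().any():
        row = int(frame[["time_s", "depth_m"]].isna().any(axis=1).idxmax())
        raise ValueError(f"{path.name}: missing value at row {row}")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if (species is None or body_mass is None) and sidecar.exists():
        meta = json.loads(sidecar.read_text())
        species = species or meta.get("species")
        body_mass = body_mass or meta.get("body_mass")
        id = id or meta.get("id", "")
    if species is None or body_mass is None:
        raise ValueError("species and body_mass are required (argument or sidecar)")
    times = frame["time_s"].to_numpy(dtype=float)
    times = times - times[0]
    interval = float(np.median(np.diff(times))) if times.size > 1 else float("nan")
    return RawRecord(
        times=times,
        depths=frame["depth_m"].to_numpy(dtype=float),
        sampling_interval=interval,
        species=Species(species),
        body_mass=float(body_mass),
        id=id or path.stem,
    )


def regularize(record: RawRecord, offset: float = 2.0) -> DepthSeries:
    """Interpolate a record to 1 Hz and subtract the surface offset.

    Depth is linearly interpolated between native samples onto integer
    seconds, then ``offset`` metres (default 2) are subtracted and the
    result clipped at 0 so surfacings read exactly 0.
    """
    if record.times.size < 2:
        raise ValueError("record must contain at least 2 samples")
    t0 = record.times[0]
    t_grid = t0 + np.arange(0.0, np.floor(record.times[-1] - t0) + 1.0)
    depths = np.interp(t_grid, record.times, record.depths)
    depths = np.maximum(0.0, depths - offset)
    return DepthSeries(depths=depths, offset_applied=offset, t0=record.times[0])


def segment_dives(series: DepthSeries) -> list[Dive]:
    """Split a regularized series into dives (maximal runs of depth > 0)."""
    wet = series.depths > 0.0
    if not wet.any():
        return []
    edges = np.flatnonzero(np.diff(wet.astype(np.int8)))
    starts = [0] if wet[0] else []
    starts += [int(i) + 1 for i in edges if not wet[i]]
    ends = [int(i) + 1 for i in edges if wet[i]]
    if wet[-1]:
        ends.append(int(wet.size))
    dives = []
    for s, e in zip(starts, ends):
        seg = series.depths[s:e]
        dives.append(Dive(
            start_index=s,
            end_index=e,
            max_depth=float(seg.max()),
            mean_depth=float(seg.mean()),
            truncated=(s == 0 and wet[0]) or (e == wet.size and wet[-1]),
        ))
    return dives


def bin_dive(max_depth: float) -> str:
    """Depth-bin label: shallow < 30 m, medium 30-90 m, deep > 90 m."""
    if max_depth < 0:
        raise ValueError("max_depth must be >= 0")
    if max_depth < SHALLOW_MAX:
        return "shallow"
    if max_depth <= MEDIUM_MAX:
        return "medium"
    return "deep"


def dive_table(dives: list[Dive], id: str = "") -> pd.DataFrame:
    """One row per dive: start, duration, depths, bin, truncation flag."""
    return pd.DataFrame({
        "id": id,
        "start_s": [d.start_index for d in dives],
        "duration_s": [d.duration for d in dives],
        "max_depth_m": [d.max_depth for d in dives],
        "mean_depth_m": [d.mean_depth for d in dives],
        "bin": [d.bin for d in dives],
        "truncated": [d.truncated for d in dives],
    })


def summarize(dives: list[Dive]) -> pd.DataFrame:
    """Per-bin dive summary: duration and max depth (mean, sample SD), counts.

    Proportions are percentages of all dives and sum to 100.  Bins with
    no dives appear with count 0 and NaN statistics.
    """
    if not dives:
        raise ValueError("no dives to summarize")
    table = dive_table(dives)
    rows = []
    n_total = len(table)
    for b in BINS:
        sub = table[table["bin"] == b]
        rows.append({
            "bin": b,
            "n": len(sub),
            "proportion_pct": 100.0 * len(sub) / n_total,
            "duration_mean_s": sub["duration_s"].mean(),
            "duration_sd_s": sub["duration_s"].std(ddof=1),
            "max_depth_mean_m": sub["max_depth_m"].mean(),
            "max_depth_sd_m": sub["max_depth_m"].std(ddof=1),
        })
    return pd.DataFrame(rows).set_index("bin")
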