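"""Synthetic dive bouts with the statistical structure of real TDR records.

No raw turtle tag data are distributed, so simulated dive bouts stand in
for them: each animal's published per-bin dive statistics (proportion of
shallow/medium/deep dives, dive duration and maximum depth, mean and SD)
drive a generator that emits 1 Hz depth series in exactly the shape the
rest of the pipeline expects.  Dives are trapezoidal
(descent - bottom - ascent) with a short ascent pause around 10-20 m,
where sea turtles of all three study species tend to slow down before
surfacing; durations and depths are truncated-normal draws, with depths
truncated to the dive's depth-bin interval so realized bin proportions
match the specification.

The step-wise forced-dive profile used for model validation (a staircase
of equal pressure increments to 19.4 ATA in a hyperbaric chamber) is
also provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml
from scipy.stats import truncnorm

from .dive_records import BINS, DepthSeries, MEDIUM_MAX, SHALLOW_MAX
from .parameters import Species

__all__ = ["BinSpec", "BoutSpec", "load_bout_spec", "available_bout_specs",
           "generate_bout", "forced_dive_profile"]

# depth-bin intervals for truncating max-depth draws (m)
_BIN_DEPTH_RANGE = {
    "shallow": (1.0, SHALLOW_MAX - 1e-6),
    "medium": (SHALLOW_MAX, MEDIUM_MAX),
    "deep": (MEDIUM_MAX + 1e-6, 1200.0),
}
_MIN_DURATION_S = 10.0


@dataclass(frozen=True)
class BinSpec:
    """Dive statistics for one depth bin."""

    proportion_pct: float
    duration_mean_s: float
    duration_sd_s: float
    max_depth_mean_m: float
    max_depth_sd_m: float

    def __post_init__(self) -> None:
        if self.proportion_pct < 0:
            raise ValueError("proportion must be >= 0")
        if self.proportion_pct > 0 and (self.duration_mean_s <= 0
                                        or self.max_depth_mean_m <= 0):
            raise ValueError("duration and depth means must be positive")


@dataclass(frozen=True)
class BoutSpec:
    """Recipe for one synthetic dive bout.

    ``bins`` maps bin label -> :class:`BinSpec`; proportions are
    normalized to 100.  Surface intervals and dive-shape parameters are
    not recoverable from published summaries and carry declared
    defaults: surface interval 120 +/- 60 s, 40% of the dive spent at
    the bottom, and a 10 s ascent pause at 15 m for dives deeper than
    20 m.
    """

    species: Species
    body_mass: float
    n_dives: int
    seed: int
    bins: dict[str, BinSpec]
    surface_interval_mean_s: float = 120.0
    surface_interval_sd_s: float = 60.0
    bottom_fraction: float = 0.4
    ascent_pause_depth_m: float = 15.0
    ascent_pause_s: float = 10.0
    id: str = ""

    def __post_init__(self) -> None:
        if self.n_dives < 1:
            raise ValueError("n_dives must be >= 1")
        total = sum(b.proportion_pct for b in self.bins.values())
        if total <= 0:
            raise ValueError("bin proportions must sum to a positive value")
        if not 0.0 < self.bottom_fraction < 1.0:
            raise ValueError("bottom_fraction must lie in (0, 1)")

    def proportions(self) -> dict[str, float]:
        """Normalized bin probabilities."""
        total = sum(b.proportion_pct for b in self.bins.values())
        return {k: b.proportion_pct / total for k, b in self.bins.items()}


def _load_bout_table() -> dict:
    with resources.files("divegas.data").joinpath("bout_specs.yaml").open() as fh:
        return yaml.safe_load(fh)


_BOUT_TABLE = _load_bout_table()


def available_bout_specs() -> list[str]:
    return sorted(_BOUT_TABLE["animals"])


def load_bout_spec(animal_id: str, n_dives: int, seed: int, **overrides) -> BoutSpec:
    """Bout spec for one published animal ID (e.g. ``"Dc1"``, ``"Cm1"``)."""
    try:
        row = _BOUT_TABLE["animals"][animal_id]
    except KeyError:
        raise ValueError(
            f"unknown animal {animal_id!r}; known: {available_bout_specs()}") from None
    bins = {}
    for b in BINS:
        entry = row.get(b)
        if entry is None:
            continue
        bins[b] = BinSpec(
            proportion_pct=float(entry["proportion"]),
            duration_mean_s=float(entry["duration"][0]),
            duration_sd_s=float(entry["duration"][1]),
            max_depth_mean_m=float(entry["max_depth"][0]),
            max_depth_sd_m=float(entry["max_depth"][1]),
        )
    return BoutSpec(
        species=Species(row["species"]),
        body_mass=float(row["body_mass"]),
        n_dives=n_dives,
        seed=seed,
        bins=bins,
        id=animal_id,
        **overrides,
    )


def _draw_truncnorm(rng, mean, sd, lo, hi):
    if sd <= 0 or hi <= lo:
        return float(min(max(mean, lo), hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _dive_profile(duration_s: int, max_depth: float, spec: BoutSpec) -> np.ndarray:
    """Trapezoidal dive: descent, bottom, ascent with an optional pause.

    Every sample is strictly submerged (> 0 m); the run length equals
    ``duration_s`` exactly so segmentation round-trips the drawn
    duration.
    """
    n = int(duration_s)
    n_bottom = max(1, int(round(spec.bottom_fraction * n)))
    n_travel = n - n_bottom
    n_desc = max(1, n_travel // 2)
    n_asc = max(1, n_travel - n_desc)
    if n_desc + n_bottom + n_asc > n:      # tiny dives
        n_bottom = max(1, n - n_desc - n_asc)
    desc = max_depth * np.arange(1, n_desc + 1) / n_desc
    bottom = np.full(n_bottom, max_depth)
    asc = max_depth * np.arange(n_asc - 1, -1, -1.0) / n_asc
    asc = np.maximum(asc, 0.1)             # stay submerged until the final surfacing
    profile = np.concatenate([desc, bottom, asc])[:n]
    if max_depth > 20.0 and spec.ascent_pause_s >= 1:
        # hold the ascent at the pause depth for a few samples
        idx = len(desc) + n_bottom + int(np.argmin(
            np.abs(asc - spec.ascent_pause_depth_m)))
        pause = np.full(int(spec.ascent_pause_s), spec.ascent_pause_depth_m)
        profile = np.concatenate([profile[:idx], pause, profile[idx:]])[:len(profile)]
    return np.maximum(profile, 0.1)


def generate_bout(spec: BoutSpec) -> DepthSeries:
    """Generate a seeded 1 Hz dive bout.

    The output starts and ends at the surface; every dive is separated
    by at least one surface sample, so ``segment_dives`` recovers
    exactly ``n_dives`` dives with the drawn durations.
    """
    rng = np.random.default_rng(spec.seed)
    labels = list(spec.bins)
    probs = [spec.proportions()[k] for k in labels]
    pieces = [np.zeros(5)]
    for _ in range(spec.n_dives):
        b = labels[rng.choice(len(labels), p=probs)]
        bs = spec.bins[b]
        lo_d, hi_d = _BIN_DEPTH_RANGE[b]
        duration = _draw_truncnorm(rng, bs.duration_mean_s, bs.duration_sd_s,
                                   _MIN_DURATION_S, 20 * bs.duration_mean_s)
        depth = _draw_truncnorm(rng, bs.max_depth_mean_m, bs.max_depth_sd_m, lo_d, hi_d)
        pieces.append(_dive_profile(int(round(duration)), depth, spec))
        si = _draw_truncnorm(rng, spec.surface_interval_mean_s,
                             spec.surface_interval_sd_s, 10.0,
                             20 * spec.surface_interval_mean_s)
        pieces.append(np.zeros(int(round(si))))
    return DepthSeries(depths=np.concatenate(pieces), offset_applied=0.0)


def forced_dive_profile(target_p_ata: float = 19.4, n_steps: int = 6,
                        step_hold_s: int = 600, surface_pad_s: int = 60) -> DepthSeries:
    """Step-wise forced-dive (hyperbaric chamber) profile.

    Pressure rises in ``n_steps`` equal increments to ``target_p_ata``
    (19.4 ATA = 184 m), holds each step for ``step_hold_s`` seconds,
    then descends the same staircase in reverse back to the surface.
    The published account gives the peak pressure but not the step
    schedule; the symmetric staircase with 10 min holds is this
    package's documented stand-in.
    """
    if target_p_ata <= 1.0:
        raise ValueError("target pressure must exceed 1 ATA")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    depths = [np.zeros(surface_pad_s)]
    step_depths = [(target_p_ata - 1.0) * (k / n_steps) * 10.0
                   for k in range(1, n_steps + 1)]
    for d in step_depths:
        depths.append(np.full(step_hold_s, d))
    for d in reversed(step_depths[:-1]):
        depths.append(np.full(step_hold_s, d))
    depths.append(np.zeros(surface_pad_s))
    return DepthSeries(depths=np.concatenate(depths), offset_applied=0.0)
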