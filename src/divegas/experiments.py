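"""End-dive N2 metrics, model-variant comparisons and supersaturation ratios.

The gas-embolism risk index is the mixed-venous N2 tension at the end of
each dive: the mean over the final 5 s of submergence, aggregated
(mean and maximum) per depth bin.  Model variants (body condition,
surface and diving cardiac output) are compared to the control as
percent change, 100 * (variant - control) / control.  Supersaturation
is expressed two ways: referenced to the surface-equilibrium N2 tension
(PN2 / 0.741 - the convention that reproduces the published M-ratios)
or to ambient pressure ((PN2 - Pamb) / Pamb).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gas_dynamics as gd
from .dive_records import BINS, DepthSeries, Dive, dive_table, segment_dives
from .parameters import VARIANTS, GasConstants, TurtleConfig, make_variant

__all__ = [
    "END_DIVE_WINDOW_S",
    "EndDiveMetrics",
    "ExperimentBundle",
    "end_dive_pn2",
    "percent_change",
    "supersaturation_ratio",
    "supersaturation_field",
    "run_suite",
]

END_DIVE_WINDOW_S = 5


@dataclass
class EndDiveMetrics:
    """Per-dive end-dive mixed-venous PN2 plus per-bin aggregates.

    ``per_dive`` has one row per completed (non-truncated) dive with its
    bin and end-dive PN2; ``per_bin`` indexes mean/max/n by depth bin.
    """

    per_dive: pd.DataFrame
    per_bin: pd.DataFrame

    @property
    def overall_mean(self) -> float:
        return float(self.per_dive["end_pn2"].mean())

    @property
    def overall_max(self) -> float:
        return float(self.per_dive["end_pn2"].max())


def end_dive_pn2(result: gd.SimulationResult, dives: list[Dive],
                 window_s: int = END_DIVE_WINDOW_S,
                 exclude_truncated: bool = True,
                 column: str = "pn2_venous") -> EndDiveMetrics:
    """End-dive PN2: mean of ``column`` over the last ``window_s`` in-dive samples.

    Dives shorter than the window use all their samples and are flagged
    ``short_window``.  Truncated dives (cut by the record edge) are
    excluded by default.
    """
    kept = [d for d in dives if not (exclude_truncated and d.truncated)]
    if not kept:
        raise ValueError("no completed dives to score")
    pn2 = result.frame[column].to_numpy()
    rows = []
    for d in kept:
        lo = max(d.start_index, d.end_index - window_s)
        rows.append({
            "start_s": d.start_index,
            "duration_s": d.duration,
            "max_depth_m": d.max_depth,
            "bin": d.bin,
            "end_pn2": float(pn2[lo:d.end_index].mean()),
            "short_window": d.duration < window_s,
        })
    per_dive = pd.DataFrame(rows)
    agg = []
    for b in BINS:
        sub = per_dive[per_dive["bin"] == b]["end_pn2"]
        agg.append({"bin": b, "n": len(sub),
                    "mean_end_pn2": sub.mean(), "max_end_pn2": sub.max()})
    return EndDiveMetrics(per_dive=per_dive, per_bin=pd.DataFrame(agg).set_index("bin"))


def percent_change(control: EndDiveMetrics, variant: EndDiveMetrics) -> pd.DataFrame:
    """Percent change of mean and max end-dive PN2, per bin and overall.

    100 * (variant - control) / control; identically 0 for
    control-vs-control.  Raises if a control statistic is 0.
    """
    rows = []
    pairs = [(b, control.per_bin.loc[b], variant.per_bin.loc[b]) for b in BINS]
    for b, c, v in pairs:
        row = {"bin": b}
        for stat in ("mean_end_pn2", "max_end_pn2"):
            cv = c[stat]
            if pd.isna(cv):
                row[f"pct_change_{stat}"] = np.nan
            elif cv == 0:
                raise ZeroDivisionError(f"control {stat} is zero in bin {b}")
            else:
                row[f"pct_change_{stat}"] = 100.0 * (v[stat] - cv) / cv
        rows.append(row)
    rows.append({
        "bin": "all",
        "pct_change_mean_end_pn2":
            100.0 * (variant.overall_mean - control.overall_mean) / control.overall_mean,
        "pct_change_max_end_pn2":
            100.0 * (variant.overall_max - control.overall_max) / control.overall_max,
    })
    return pd.DataFrame(rows).set_index("bin")


def supersaturation_ratio(pn2, mode: str = "surface_n2_referenced",
                          p_amb=1.0, gas: GasConstants = GasConstants()):
    """Supersaturation (M-) ratio for a mixed-venous N2 tension.

    ``surface_n2_referenced`` (default): PN2 / surface PN2 (0.741 ATA) -
    the reading consistent with the published ratios.
    ``ambient_referenced``: (PN2 - Pamb) / Pamb.
    """
    pn2 = np.asarray(pn2, dtype=float)
    if np.any(pn2 < 0):
        raise ValueError("PN2 must be >= 0")
    if mode == "surface_n2_referenced":
        r = pn2 / gas.surface_pn2
    elif mode == "ambient_referenced":
        r = (pn2 - np.asarray(p_amb, dtype=float)) / np.asarray(p_amb, dtype=float)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return r if r.ndim else float(r)


def supersaturation_field(result: gd.SimulationResult) -> pd.DataFrame:
    """Per-sample supersaturation of mixed venous blood, both references."""
    f = result.frame
    return pd.DataFrame({
        "ambient_referenced": (f["pn2_venous"] - f["p_amb"]) / f["p_amb"],
        "surface_n2_referenced": supersaturation_ratio(
            f["pn2_venous"].to_numpy(),
            gas=result.config.gas if result.config else GasConstants()),
    })


@dataclass
class ExperimentBundle:
    """Results of the control + six-variant suite on one record."""

    dives: pd.DataFrame                        # dive table of the series
    metrics: dict[str, EndDiveMetrics]         # per variant
    comparisons: dict[str, pd.DataFrame]       # percent change vs control
    control_result: gd.SimulationResult | None = None
    events: dict[str, list] = field(default_factory=dict)


def run_suite(series: DepthSeries, config: TurtleConfig,
              variants: tuple[str, ...] = VARIANTS,
              keep_control_trajectory: bool = True) -> ExperimentBundle:
    """Simulate the control and each variant on one depth series.

    Deterministic given inputs.  Full trajectories are discarded after
    scoring (except the control's, kept for supersaturation plots) to
    bound memory on long records.
    """
    dives = segment_dives(series)
    metrics: dict[str, EndDiveMetrics] = {}
    comparisons: dict[str, pd.DataFrame] = {}
    events: dict[str, list] = {}
    control_result = None
    for name in variants:
        cfg = make_variant(config, name)
        result = gd.simulate(series, cfg)
        metrics[name] = end_dive_pn2(result, dives)
        events[name] = result.events
        if name == "control" and keep_control_trajectory:
            control_result = result
        del result
    for name in variants:
        comparisons[name] = percent_change(metrics["control"], metrics[name])
    return ExperimentBundle(
        dives=dive_table(dives),
        metrics=metrics,
        comparisons=comparisons,
        control_result=control_result,
        events=events,
    )
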