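"""Regularize a time-depth record and summarize its dives.

Builds a small synthetic green-turtle record at a 10 s tag sampling
interval, regularizes it to 1 Hz with the 2 m surface offset, segments
it into dives and prints the per-bin summary table (shallow < 30 m,
medium 30-90 m, deep > 90 m).
"""

import numpy as np

import divegas as dv

# a synthetic Cm1-style bout stands in for a tag download
series = dv.generate_bout(dv.load_bout_spec("Cm1", n_dives=40, seed=12))

# pretend it came off a 10 s tag with the usual ~2 m surface bias
raw = dv.RawRecord(
    times=series.times[::10],
    depths=series.depths[::10] + 2.0,
    sampling_interval=10.0,
    species=dv.Species.GREEN,
    body_mass=71.0,
    id="Cm1-synthetic",
)

regular = dv.regularize(raw, offset=2.0)       # 1 Hz, offset removed
dives = dv.segment_dives(regular)
summary = dv.summarize(dives)

print(f"record: {len(regular)} s at 1 Hz, {len(dives)} dives")
print(summary.round(1))
print()
print("Each row is one depth bin: n dives, their share of all dives (%),")
print("and dive duration / maximum depth as mean +/- sample SD.")
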