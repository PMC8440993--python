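"""Reading, regularizing and segmenting time-depth records."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import divegas as dv
from divegas.dive_records import RawRecord


def _record(times, depths, **kw):
    kw.setdefault("sampling_interval", 10.0)
    kw.setdefault("species", dv.Species.GREEN)
    kw.setdefault("body_mass", 70.0)
    return RawRecord(times=np.asarray(times, float),
                     depths=np.asarray(depths, float), **kw)


class TestReadTdr:
    def test_reads_csv_with_sidecar_free_metadata(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("time_s,depth_m\n0,0\n10,12\n20,0\n")
        rec = dv.read_tdr(p, species="green", body_mass=70)
        assert rec.times.tolist() == [0, 10, 20]
        assert rec.depths.tolist() == [0, 12, 0]
        assert rec.sampling_interval == 10

    @pytest.mark.parametrize("body, match", [
        ("time_s,depth_m\n0,0\n10,5\n5,0\n", "non-monotone"),
        ("time_s,depth_m\n0,0\n10,-1\n", "negative depth"),
        ("time_s,wrong\n0,0\n", "missing required column"),
    ])
    def test_bad_input_is_a_hard_error(self, tmp_path, body, match):
        p = tmp_path / "bad.csv"
        p.write_text(body)
        with pytest.raises(ValueError, match=match):
            dv.read_tdr(p, species="green", body_mass=70)

    def test_sidecar_metadata(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("time_s,depth_m\n0,0\n10,3\n")
        (tmp_path / "t.csv.meta.json").write_text(
            '{"species": "leatherback", "body_mass": 350, "id": "Dc1"}')
        rec = dv.read_tdr(p)
        assert rec.species is dv.Species.LEATHERBACK
        assert rec.body_mass == 350
        assert rec.id == "Dc1"


class TestRegularize:
    def test_linear_interpolation_then_offset_clamp(self):
        rec = _record([0, 10], [0, 12])
        series = dv.regularize(rec, offset=2.0)
        expected = [0, 0, 0.4, 1.6, 2.8, 4.0, 5.2, 6.4, 7.6, 8.8, 10.0]
        np.testing.assert_allclose(series.depths, expected, atol=1e-12)
        assert series.offset_applied == 2.0

    def test_constant_two_metres_reads_as_surface(self):
        rec = _record([0, 10, 20], [2, 2, 2])
        assert np.all(dv.regularize(rec).depths == 0.0)

    def test_zero_offset_is_identity_on_constant_depth(self):
        rec = _record([0, 10], [5, 5])
        assert np.all(dv.regularize(rec, offset=0.0).depths == 5.0)

    def test_idempotent_on_1hz_series_with_zero_offset(self):
        rec = _record(np.arange(6.0), [0, 1, 3, 2, 1, 0], sampling_interval=1.0)
        once = dv.regularize(rec, offset=0.0)
        again = dv.regularize(
            _record(once.times, once.depths, sampling_interval=1.0), offset=0.0)
        np.testing.assert_array_equal(once.depths, again.depths)

    def test_too_short(self):
        with pytest.raises(ValueError, match="at least 2"):
            dv.regularize(_record([0.0], [1.0]))


def _oracle_segments(depths):
    """Brute-force run scan: (start, end, max, truncated) per wet run."""
    runs, start = [], None
    for i, d in enumerate(depths):
        if d > 0 and start is None:
            start = i
        if d <= 0 and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(depths)))
    n = len(depths)
    return [(s, e, max(depths[s:e]),
             (s == 0 and depths[0] > 0) or (e == n and depths[-1] > 0))
            for s, e in runs]


class TestSegmentDives:
    def test_two_dives_example(self):
        series = dv.DepthSeries(np.array([0, 3, 8, 3, 0, 0, 5, 0], float))
        dives = dv.segment_dives(series)
        assert [(d.duration, d.max_depth) for d in dives] == [(3.0, 8.0), (1.0, 5.0)]
        assert not any(d.truncated for d in dives)

    def test_all_surface_gives_no_dives(self):
        assert dv.segment_dives(dv.DepthSeries(np.zeros(50))) == []

    def test_boundary_dive_is_truncated(self):
        dives = dv.segment_dives(dv.DepthSeries(np.array([1.0, 1.0, 0.0])))
        assert len(dives) == 1
        assert dives[0].duration == 2.0 and dives[0].truncated

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=120, allow_nan=False),
                    min_size=1, max_size=400))
    def test_matches_brute_force_oracle(self, depths):
        series = dv.DepthSeries(np.asarray(depths))
        got = [(d.start_index, d.end_index, d.max_depth, d.truncated)
               for d in dv.segment_dives(series)]
        assert got == _oracle_segments(depths)


class TestBinning:
    @pytest.mark.parametrize("depth, label", [
        (25.0, "shallow"), (29.999, "shallow"),
        (30.0, "medium"), (90.0, "medium"),
        (96.9, "deep"), (90.001, "deep"),
    ])
    def test_bin_boundaries(self, depth, label):
        assert dv.bin_dive(depth) == label


class TestSummarize:
    @staticmethod
    def _dive(duration, depth, start=1):
        return dv.Dive(start_index=start, end_index=start + int(duration),
                       max_depth=depth, mean_depth=depth / 2)

    def test_two_shallow_dives_hand_computed(self):
        s = dv.summarize([self._dive(100, 10), self._dive(200, 20)])
        assert s.loc["shallow", "proportion_pct"] == 100.0
        assert s.loc["shallow", "duration_mean_s"] == 150.0
        assert s.loc["shallow", "duration_sd_s"] == pytest.approx(70.7107, abs=1e-3)
        assert s.loc["medium", "n"] == 0

    def test_one_dive_per_bin(self):
        s = dv.summarize([self._dive(60, 5), self._dive(60, 50), self._dive(60, 150)])
        np.testing.assert_allclose(s["proportion_pct"], [100 / 3] * 3)

    def test_proportions_sum_to_100(self, mixed_bout_series):
        dives = dv.segment_dives(mixed_bout_series)
        s = dv.summarize(dives)
        assert s["proportion_pct"].sum() == pytest.approx(100.0, abs=0.1)
        assert s["n"].sum() == len(dives)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            dv.summarize([])


def test_dive_table_roundtrips_through_csv(tmp_path, mixed_bout_series):
    table = dv.dive_table(dv.segment_dives(mixed_bout_series), id="synthetic")
    path = tmp_path / "dives.csv"
    table.to_csv(path, index=False)
    back = pd.read_csv(path)
    assert len(back) == len(table)
    assert set(back.columns) == set(table.columns)
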