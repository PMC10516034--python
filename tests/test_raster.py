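"""Spike raster data model, event binning and file round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from tricorr import (
    EventList,
    InputError,
    RasterFormatError,
    SpikeRaster,
    bin_events,
    read_raster,
    write_raster,
)


class TestSpikeRaster:
    def test_rejects_non_binary(self):
        with pytest.raises(InputError, match="0 or 1"):
            SpikeRaster(np.array([[0, 2], [1, 0]]))

    def test_rejects_empty_and_bad_metadata(self):
        with pytest.raises(InputError):
            SpikeRaster(np.zeros((0, 5)))
        with pytest.raises(InputError):
            SpikeRaster(np.zeros((2, 2)), bin_width=0.0)
        with pytest.raises(InputError):
            SpikeRaster(np.zeros((2, 2)), channel_ids=("a",))

    def test_basic_properties(self):
        r = SpikeRaster(np.eye(3, dtype=int), bin_width=0.5)
        assert (r.n_channels, r.n_bins, r.spike_count) == (3, 3, 3)
        assert r.duration == 1.5

    def test_crop_shifts_origin(self):
        r = SpikeRaster(np.ones((2, 10), dtype=int), bin_width=2.0)
        c = r.crop(3, 7)
        assert c.n_bins == 4 and c.t0 == 6.0
        with pytest.raises(InputError):
            r.crop(5, 20)


class TestBinEvents:
    def test_empty_events_give_zero_raster(self):
        r = bin_events(EventList(()), 1.0, ["c0", "c1", "c2", "c3"], 10.0)
        assert r.data.shape == (4, 10)
        assert r.spike_count == 0

    def test_multiple_events_in_one_bin_clip_to_one(self):
        ev = EventList((("c1", 0.2), ("c1", 0.7)))
        r = bin_events(ev, 1.0, ["c0", "c1"], 5.0)
        assert r.spike_count == 1
        assert r.data[1, 0] == 1

    def test_half_open_bins(self):
        # an event exactly at a bin edge belongs to the later bin
        r = bin_events(EventList((("c0", 2.0),)), 1.0, ["c0"], 5.0)
        assert r.data[0, 2] == 1 and r.data[0, 1] == 0

    def test_unknown_channel_and_late_event_error(self):
        with pytest.raises(InputError, match="unknown channel"):
            bin_events(EventList((("x", 1.0),)), 1.0, ["c0"], 5.0)
        with pytest.raises(InputError, match="duration"):
            bin_events(EventList((("c0", 5.0),)), 1.0, ["c0"], 5.0)

    def test_event_times_validated(self):
        with pytest.raises(InputError):
            EventList((("c0", -1.0),))
        with pytest.raises(InputError):
            EventList((("c0", float("nan")),))

    def test_feedforward_event_layout_has_48_spikes(self, ff_raster):
        """16 three-spike motifs laid out as events bin back to 48 spikes."""
        chans, bins = np.nonzero(ff_raster.data)
        ev = EventList(
            tuple(
                (ff_raster.channel_ids[c], b * ff_raster.bin_width + 0.1)
                for c, b in zip(chans, bins)
            )
        )
        assert len(ev) == 48
        r = bin_events(ev, ff_raster.bin_width, ff_raster.channel_ids,
                       ff_raster.duration)
        assert r.spike_count == 48
        assert np.array_equal(r.data, ff_raster.data)


class TestRoundTrip:
    @settings(max_examples=25, deadline=None)
    @given(arrays(np.uint8, st.tuples(st.integers(1, 10), st.integers(1, 25)),
                  elements=st.integers(0, 1)))
    def test_dense_round_trip_identity(self, tmp_path_factory, data):
        path = tmp_path_factory.mktemp("rt") / "r.txt"
        r = SpikeRaster(data)
        write_raster(r, path, format="dense")
        back = read_raster(path, format="dense")
        assert np.array_equal(back.data, r.data)

    def test_event_csv_round_trip(self, tmp_path, ff_raster):
        path = tmp_path / "events.csv"
        write_raster(ff_raster, path, format="event-csv")
        assert sum(1 for _ in open(path)) == 49  # header + 48 events
        back = read_raster(path, format="event-csv",
                           bin_width=ff_raster.bin_width,
                           channel_order=ff_raster.channel_ids,
                           duration=ff_raster.duration)
        assert back.spike_count == 48
        assert np.array_equal(back.data, ff_raster.data)

    def test_write_is_deterministic(self, tmp_path, ff_raster):
        p1, p2 = tmp_path / "a.txt", tmp_path / "b.txt"
        write_raster(ff_raster, p1)
        write_raster(ff_raster, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_all_zero_raster_writes_only_zeros(self, tmp_path):
        path = tmp_path / "z.txt"
        write_raster(SpikeRaster(np.zeros((3, 4), dtype=int)), path)
        assert set(path.read_text().split()) == {"0"}


class TestFormatErrors:
    def test_dense_non_binary_entry(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("0 1 0\n0 2 0\n")
        with pytest.raises(RasterFormatError, match="non-binary"):
            read_raster(path)

    def test_dense_ragged_rows(self, tmp_path):
        path = tmp_path / "ragged.txt"
        path.write_text("0 1 0\n0 1\n")
        with pytest.raises(RasterFormatError, match="ragged"):
            read_raster(path)

    def test_event_csv_bad_header(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("chan,when\nc0,1.0\n")
        with pytest.raises(RasterFormatError, match="header"):
            read_raster(path, format="event-csv")
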