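"""Triple-correlation engine vs. the nested-loop oracle, and its invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from tricorr import (
    InputError,
    LagTensor,
    LagWindow,
    SpikeRaster,
    brute_force_oracle,
    compute_triple_correlation,
    generate_random_raster,
    load_tensor_hdf5,
    save_tensor_csv,
    save_tensor_hdf5,
    tensor_slice,
)

W22 = LagWindow(2, 2)


def raster_from(coords, shape=(4, 6)):
    data = np.zeros(shape, dtype=np.uint8)
    for n, t in coords:
        data[n, t] = 1
    return SpikeRaster(data)


class TestOracle:
    def test_all_zero_raster_gives_all_zero_tensor(self):
        t = brute_force_oracle(raster_from([]), W22)
        assert not t.values.any()

    def test_two_spike_enumeration(self):
        """Every nonzero cell of the two-point raster, enumerated by hand.

        Spikes at (0,0) and (1,1): the only triplets are the two
        self-triples (zero-lag cell = spike count 2) and the six ways of
        pointing one or both lag vectors from one spike to the other.
        """
        t = brute_force_oracle(raster_from([(0, 0), (1, 1)], shape=(3, 3)),
                               LagWindow(1, 1))
        expected = {
            (0, 0, 0, 0): 2,
            (1, 1, 0, 0): 1, (-1, -1, 0, 0): 1,
            (0, 0, 1, 1): 1, (0, 0, -1, -1): 1,
            (1, 1, 1, 1): 1, (-1, -1, -1, -1): 1,
        }
        for n1 in range(-1, 2):
            for t1 in range(-1, 2):
                for n2 in range(-1, 2):
                    for t2 in range(-1, 2):
                        assert t.value(n1, t1, n2, t2) == expected.get(
                            (n1, t1, n2, t2), 0
                        )


class TestFastPath:
    def test_single_spike_is_a_delta_at_zero_lag(self):
        t = compute_triple_correlation(raster_from([(3, 5)], shape=(6, 8)),
                                       LagWindow(1, 1))
        assert t.value(0, 0, 0, 0) == 1
        assert t.values.sum() == 1

    @pytest.mark.parametrize("p", [0.05, 0.1, 0.2])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_oracle_on_random_rasters(self, p, seed):
        rng = np.random.default_rng(1000 * seed + int(p * 100))
        r = generate_random_raster((6, 15), p, rng=rng)
        assert np.array_equal(
            compute_triple_correlation(r, W22).values,
            brute_force_oracle(r, W22).values,
        )

    def test_feedforward_fixture_zero_lag_is_48(self, ff_tensor, ff_raster):
        assert ff_tensor.value(0, 0, 0, 0) == 48 == ff_raster.spike_count

    def test_average_flag_rescales_only(self):
        r = raster_from([(1, 1), (2, 3)])
        raw = compute_triple_correlation(r, W22)
        avg = compute_triple_correlation(r, W22, average=True)
        assert np.allclose(avg.values, raw.values / (4 * 6))

    def test_valid_boundary_counts_interior_references_only(self):
        # spikes: one interior, one on the edge
        r = raster_from([(2, 3), (0, 0)], shape=(5, 7))
        t = compute_triple_correlation(r, W22, boundary="valid")
        assert t.value(0, 0, 0, 0) == 1  # only the interior spike is a reference

    def test_window_larger_than_raster_warns(self):
        r = raster_from([(1, 1)], shape=(3, 3))
        with pytest.warns(UserWarning, match="edge-dominated"):
            compute_triple_correlation(r, LagWindow(4, 4))

    def test_non_binary_raster_rejected(self):
        r = raster_from([(1, 1)])
        object.__setattr__(r, "data", r.data + r.data)  # corrupt past validation
        with pytest.raises(InputError, match="binary"):
            compute_triple_correlation(r, W22)


class TestInvariants:
    @settings(max_examples=20, deadline=None)
    @given(arrays(np.uint8, (5, 9), elements=st.integers(0, 1)))
    def test_zero_lag_identity_and_exchange_symmetry(self, data):
        """value(0,0,0,0) == spike count; the two lagged factors commute."""
        r = SpikeRaster(data)
        t = compute_triple_correlation(r, W22)
        assert t.value(0, 0, 0, 0) == r.spike_count
        assert np.array_equal(t.values, t.values.transpose(2, 3, 0, 1))

    def test_mirror_symmetry_of_pairwise_slice_for_interior_spikes(self, ff_tensor):
        """For spikes >= window-width from edges, slice(n1,t1) == slice(-n1,-t1)."""
        sl = tensor_slice(ff_tensor, n2=0, t2=0)
        assert np.array_equal(sl, sl[::-1, ::-1])

    def test_adding_a_spike_never_decreases_any_cell(self):
        rng = np.random.default_rng(3)
        r = generate_random_raster((6, 12), 0.15, rng=rng)
        base = compute_triple_correlation(r, W22).values
        zeros = np.argwhere(r.data == 0)
        n, t = zeros[rng.integers(len(zeros))]
        data = r.data.copy()
        data[n, t] = 1
        grown = compute_triple_correlation(SpikeRaster(data), W22).values
        assert (grown >= base).all()


class TestSlice:
    def test_pairwise_slice_of_fixture_reads_48_and_16s(self, ff_tensor):
        sl = tensor_slice(ff_tensor, n2=0, t2=0)
        S, T = 5, 4
        assert sl[S, T] == 48
        for dn, dt in [(1, 1), (2, 3), (1, 2)]:  # the motif's pairwise lags
            assert sl[S + dn, T + dt] == 16
            assert sl[S - dn, T - dt] == 16

    def test_slice_of_zero_tensor_is_zero(self):
        t = brute_force_oracle(raster_from([]), W22)
        assert not tensor_slice(t, n1=1, t1=0).any()

    def test_slice_validation(self, ff_tensor):
        with pytest.raises(IndexError):
            tensor_slice(ff_tensor, n2=99, t2=0)
        with pytest.raises(InputError):
            tensor_slice(ff_tensor, n2=0)
        with pytest.raises(InputError):
            tensor_slice(ff_tensor, n2=0, t2=0, n1=0)


class TestSerialization:
    def test_hdf5_round_trip(self, tmp_path, ff_tensor):
        path = tmp_path / "t.h5"
        save_tensor_hdf5(ff_tensor, path, bin_width=1.0)
        back = load_tensor_hdf5(path)
        assert back == ff_tensor

    def test_flat_csv_lists_every_cell(self, tmp_path):
        t = compute_triple_correlation(raster_from([(1, 1)]), LagWindow(1, 1))
        path = tmp_path / "t.csv"
        save_tensor_csv(t, path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1 + 81
        assert "0,0,0,0,1" in lines

    def test_lag_tensor_shape_checked(self):
        with pytest.raises(InputError):
            LagTensor(np.zeros((3, 3, 3, 2)), window=LagWindow(1, 1))
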