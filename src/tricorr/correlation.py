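"""Triple correlation of a spike raster over a bounded lag window.

The triple correlation relates a reference node ``r(n, t)`` to two other
nodes at spatiotemporal lags ``(n1, t1)`` and ``(n2, t2)``::

    c3(n1, t1, n2, t2) = sum over (n, t) of r(n,t) * r(n+n1, t+t1) * r(n+n2, t+t2)

Out-of-range factors are 0 (zero padding), so every raster cell serves as a
reference point.  Raw sums are stored, not averages: for a binary raster the
value at the all-zero lag quadruple then equals the spike count exactly.
Summing over all admissible lag quadruples within a window ``|n_i| <= S``,
``|t_i| <= T`` yields the 4D spatiotemporal lag distribution from which the
lag PDF and its entropy are derived.

The production path (:func:`compute_triple_correlation`) iterates over spikes
and accumulates patch outer products; :func:`brute_force_oracle` is a literal
nested-loop evaluation kept as an independent correctness reference.  The two
are bit-identical on every input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import InputError
from .raster import SpikeRaster

__all__ = [
    "LagWindow",
    "LagTensor",
    "compute_triple_correlation",
    "brute_force_oracle",
    "tensor_slice",
]


@dataclass(frozen=True)
class LagWindow:
    """Bounds of the admissible lag quadruples.

    ``S`` is the maximum spatial lag in channels, ``T`` the maximum temporal
    lag in bins; lags run over the full signed range including zero, so the
    lag tensor has ``(2S+1)^2 * (2T+1)^2`` cells.
    """

    S: int
    T: int

    def __post_init__(self) -> None:
        if self.S < 0 or self.T < 0:
            raise InputError("lag window bounds must be >= 0")

    @property
    def spatial_lags(self) -> np.ndarray:
        return np.arange(-self.S, self.S + 1)

    @property
    def temporal_lags(self) -> np.ndarray:
        return np.arange(-self.T, self.T + 1)

    @property
    def shape(self) -> tuple[int, int, int, int]:
        ns, nt = 2 * self.S + 1, 2 * self.T + 1
        return (ns, nt, ns, nt)

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.shape))


@dataclass(frozen=True)
class LagTensor:
    """4D array of summed triple-correlation contributions.

    ``values`` is indexed ``(n1, t1, n2, t2)`` with lag 0 at the centre:
    cell ``[n1 + S, t1 + T, n2 + S, t2 + T]`` holds the summed contribution
    at lag quadruple ``(n1, t1, n2, t2)``.
    """

    values: np.ndarray
    window: LagWindow
    source_spike_count: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.shape != self.window.shape:
            raise InputError(
                f"tensor shape {v.shape} does not match window shape {self.window.shape}"
            )
        object.__setattr__(self, "values", v)

    def value(self, n1: int, t1: int, n2: int, t2: int):
        """Contribution at one lag quadruple (lags in signed coordinates)."""
        S, T = self.window.S, self.window.T
        for lag, bound, name in ((n1, S, "n1"), (n2, S, "n2"), (t1, T, "t1"), (t2, T, "t2")):
            if abs(lag) > bound:
                raise IndexError(f"lag {name}={lag} outside window (S={S}, T={T})")
        return self.values[n1 + S, t1 + T, n2 + S, t2 + T]

    @property
    def total(self):
        return self.values.sum()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LagTensor):
            return NotImplemented
        return (
            self.window == other.window
            and self.source_spike_count == other.source_spike_count
            and np.array_equal(self.values, other.values)
        )


def _check_inputs(raster: SpikeRaster, window: LagWindow) -> None:
    if not np.isin(raster.data, (0, 1)).all():
        raise InputError("raster must be binary")
    if window.S >= raster.n_channels or window.T >= raster.n_bins:
        warnings.warn(
            f"lag window (S={window.S}, T={window.T}) is at least as large as the "
            f"raster ({raster.n_channels} channels x {raster.n_bins} bins); "
            "results are edge-dominated",
            stacklevel=3,
        )


def compute_triple_correlation(
    raster: SpikeRaster,
    window: LagWindow,
    average: bool = False,
    boundary: str = "pad",
    _chunk: int = 2048,
) -> LagTensor:
    """Triple correlation of ``raster`` accumulated over ``window``.

    Parameters
    ----------
    raster
        Binary spike raster.
    window
        Maximum spatial lag S (channels) and temporal lag T (bins).
    average
        If True, divide the summed contributions by the number of reference
        positions.  The default stores raw sums, under which the value at
        lag (0,0,0,0) equals the spike count; averaging only rescales the
        tensor and leaves the lag PDF and its entropy unchanged.
    boundary
        ``"pad"`` (default): out-of-range factors are 0 and every raster
        cell is a reference point.  ``"valid"``: reference points are
        restricted to cells at least S channels / T bins from every edge,
        so no factor is ever out of range.

    Notes
    -----
    Only spikes contribute, so the sum is reorganized: for each reference
    spike the binary patch of its ±S x ±T neighbourhood is extracted and the
    patch outer product is accumulated.  This is exactly the nested-loop sum
    (integer arithmetic, bit-identical to :func:`brute_force_oracle`) at
    O(spikes * window_cells^2) cost instead of O(raster_cells * window_cells^2).
    """
    _check_inputs(raster, window)
    if boundary not in ("pad", "valid"):
        raise InputError(f"boundary must be 'pad' or 'valid', got {boundary!r}")
    S, T = window.S, window.T
    N, L = raster.n_channels, raster.n_bins

    data = raster.data
    if boundary == "valid":
        if N <= 2 * S or L <= 2 * T:
            raise InputError(
                "raster too small for 'valid' boundary with this window"
            )
        ref_mask = np.zeros_like(data)
        ref_mask[S : N - S, T : L - T] = data[S : N - S, T : L - T]
        refs = np.nonzero(ref_mask)
        n_ref_positions = (N - 2 * S) * (L - 2 * T)
    else:
        refs = np.nonzero(data)
        n_ref_positions = N * L

    padded = np.zeros((N + 2 * S, L + 2 * T), dtype=np.int64)
    padded[S : S + N, T : T + L] = data

    ns, nt = 2 * S + 1, 2 * T + 1
    cells = ns * nt
    acc = np.zeros((cells, cells), dtype=np.int64)
    chans, bins = refs
    for start in range(0, chans.size, _chunk):
        c = chans[start : start + _chunk]
        b = bins[start : start + _chunk]
        # patch rows: r(n+n1, t+t1) flattened over (n1, t1) for each reference
        patches = np.empty((c.size, cells), dtype=np.int64)
        for i, (n, t) in enumerate(zip(c.tolist(), b.tolist())):
            patches[i] = padded[n : n + ns, t : t + nt].ravel()
        acc += patches.T @ patches

    values: np.ndarray = acc.reshape(ns, nt, ns, nt)
    if average:
        values = values / n_ref_positions
    return LagTensor(values, window=window, source_spike_count=raster.spike_count)


def brute_force_oracle(raster: SpikeRaster, window: LagWindow) -> LagTensor:
    """Literal nested-loop evaluation of the triple-correlation sum.

    A verification oracle for small rasters (think <= ~10^4 cells); it loops
    over every lag quadruple and every reference cell with explicit zero
    padding.  Must equal :func:`compute_triple_correlation` exactly.
    """
    _check_inputs(raster, window)
    S, T = window.S, window.T
    N, L = raster.n_channels, raster.n_bins
    r = raster.data.tolist()

    def at(n: int, t: int) -> int:
        if 0 <= n < N and 0 <= t < L:
            return r[n][t]
        return 0

    values = np.zeros(window.shape, dtype=np.int64)
    for n1 in range(-S, S + 1):
        for t1 in range(-T, T + 1):
            for n2 in range(-S, S + 1):
                for t2 in range(-T, T + 1):
                    acc = 0
                    for n in range(N):
                        for t in range(L):
                            if r[n][t]:
                                acc += at(n + n1, t + t1) * at(n + n2, t + t2)
                    values[n1 + S, t1 + T, n2 + S, t2 + T] = acc
    return LagTensor(values, window=window, source_spike_count=raster.spike_count)


def tensor_slice(tensor: LagTensor, **fixed: int) -> np.ndarray:
    """2D slice of the lag tensor at two fixed lag axes.

    ``fixed`` must assign exactly two of ``n1, t1, n2, t2`` (signed lag
    coordinates).  The result is the 2D sub-array over the two free axes —
    a slice, not a marginal: nothing is summed.

    >>> tensor_slice(t, n2=0, t2=0)[S, T]   # doctest: +SKIP
    """
    axes = ("n1", "t1", "n2", "t2")
    unknown = set(fixed) - set(axes)
    if unknown:
        raise InputError(f"unknown lag axes {sorted(unknown)}")
    if len(fixed) != 2:
        raise InputError(f"exactly two lag axes must be fixed, got {len(fixed)}")
    S, T = tensor.window.S, tensor.window.T
    offsets = {"n1": S, "t1": T, "n2": S, "t2": T}
    index: list = []
    for ax in axes:
        if ax in fixed:
            lag = fixed[ax]
            if abs(lag) > offsets[ax]:
                raise IndexError(f"lag {ax}={lag} outside window (S={S}, T={T})")
            index.append(lag + offsets[ax])
        else:
            index.append(slice(None))
    return tensor.values[tuple(index)]


def save_tensor_hdf5(tensor: LagTensor, path: str | Path, bin_width: float | None = None) -> None:
    """Serialize a lag tensor to HDF5 (dataset ``c3``, axis order n1,t1,n2,t2)."""
    import h5py

    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("c3", data=tensor.values)
        ds.attrs["S"] = tensor.window.S
        ds.attrs["T"] = tensor.window.T
        ds.attrs["spike_count"] = tensor.source_spike_count
        if bin_width is not None:
            ds.attrs["bin_width"] = bin_width


def load_tensor_hdf5(path: str | Path) -> LagTensor:
    import h5py

    with h5py.File(path, "r") as fh:
        ds = fh["c3"]
        window = LagWindow(int(ds.attrs["S"]), int(ds.attrs["T"]))
        return LagTensor(ds[()], window=window, source_spike_count=int(ds.attrs["spike_count"]))


def save_tensor_csv(tensor: LagTensor, path: str | Path) -> None:
    """Flat CSV ``n1,t1,n2,t2,value`` over all window cells (small windows)."""
    S, T = tensor.window.S, tensor.window.T
    with Path(path).open("w") as fh:
        fh.write("n1,t1,n2,t2,value\n")
        for n1 in range(-S, S + 1):
            for t1 in range(-T, T + 1):
                for n2 in range(-S, S + 1):
                    for t2 in range(-T, T + 1):
                        fh.write(
                            f"{n1},{t1},{n2},{t2},{tensor.value(n1, t1, n2, t2)}\n"
                        )
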