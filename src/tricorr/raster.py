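"""Binary spike rasters: the data model every computation consumes.

A spike raster is a channels x time-bins matrix ``r(n, t)`` with entries in
{0, 1}: 1 means the channel fired at least once in that bin.  Time bins are
half-open ``[t*dt, (t+1)*dt)`` and coordinates are 0-based.  Multiple events
falling in one bin clip to 1, because the downstream analysis is defined on
binary rasters.

Two interchange formats are supported:

* dense-delimited — whitespace-separated 0/1 integers, one channel per row;
* event CSV — header ``channel,time_ms``, one spike event per row.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import InputError, RasterFormatError

__all__ = ["SpikeRaster", "EventList", "bin_events", "read_raster", "write_raster"]


@dataclass(frozen=True)
class SpikeRaster:
    """Binary channels x time-bins spike matrix.

    Parameters
    ----------
    data
        2-D array of 0/1, shape ``(n_channels, n_bins)``.
    bin_width
        Width of one time bin in milliseconds.
    channel_ids
        Ordered channel labels, one per row.  Defaults to ``ch00, ch01, ...``.
    t0
        Time (ms) of the left edge of bin 0.
    """

    data: np.ndarray
    bin_width: float = 1.0
    channel_ids: tuple[str, ...] = field(default=())
    t0: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise InputError(f"raster must be a 2-D matrix, got shape {arr.shape}")
        if not np.isin(arr, (0, 1)).all():
            raise InputError("raster entries must all be 0 or 1")
        arr = np.ascontiguousarray(arr, dtype=np.uint8)
        object.__setattr__(self, "data", arr)
        if self.bin_width <= 0:
            raise InputError("bin_width must be positive")
        ids = self.channel_ids or tuple(f"ch{i:02d}" for i in range(arr.shape[0]))
        if len(ids) != arr.shape[0]:
            raise InputError(
                f"{len(ids)} channel_ids for {arr.shape[0]} channels"
            )
        object.__setattr__(self, "channel_ids", tuple(str(c) for c in ids))

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_bins(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in ms."""
        return self.n_bins * self.bin_width

    @property
    def spike_count(self) -> int:
        return int(self.data.sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpikeRaster):
            return NotImplemented
        return (
            np.array_equal(self.data, other.data)
            and self.bin_width == other.bin_width
            and self.channel_ids == other.channel_ids
            and self.t0 == other.t0
        )

    def crop(self, bin_start: int, bin_stop: int) -> "SpikeRaster":
        """Sub-raster over bins ``[bin_start, bin_stop)``; t0 is shifted."""
        if not (0 <= bin_start < bin_stop <= self.n_bins):
            raise InputError(
                f"crop [{bin_start}, {bin_stop}) outside raster of {self.n_bins} bins"
            )
        return SpikeRaster(
            self.data[:, bin_start:bin_stop],
            bin_width=self.bin_width,
            channel_ids=self.channel_ids,
            t0=self.t0 + bin_start * self.bin_width,
        )


@dataclass(frozen=True)
class EventList:
    """Unordered spike events as ``(channel_id, time_ms)`` records.

    Duplicates are permitted; binning clips them.  Times must be finite
    and non-negative.
    """

    records: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        recs = []
        for ch, t in self.records:
            t = float(t)
            if not np.isfinite(t) or t < 0:
                raise InputError(f"event time must be finite and >= 0, got {t}")
            recs.append((str(ch), t))
        object.__setattr__(self, "records", tuple(recs))

    def __len__(self) -> int:
        return len(self.records)

    @property
    def channels(self) -> set[str]:
        return {ch for ch, _ in self.records}


def bin_events(
    events: EventList,
    bin_width: float,
    channel_order: Sequence[str],
    duration: float,
) -> SpikeRaster:
    """Bin an event list into a binary raster.

    Entry ``(n, t)`` is 1 iff at least one event of channel ``n`` falls in
    ``[t * bin_width, (t+1) * bin_width)``; multiple events per bin clip to 1.

    Raises
    ------
    InputError
        If an event's channel is not in ``channel_order`` or its time is
        at or beyond ``duration``.
    """
    if bin_width <= 0:
        raise InputError("bin_width must be positive")
    if duration <= 0:
        raise InputError("duration must be positive")
    order = [str(c) for c in channel_order]
    index = {c: i for i, c in enumerate(order)}
    if len(index) != len(order):
        raise InputError("channel_order contains duplicate labels")
    n_bins = int(np.ceil(duration / bin_width))
    data = np.zeros((len(order), n_bins), dtype=np.uint8)
    for ch, t in events.records:
        if ch not in index:
            raise InputError(f"unknown channel label {ch!r}")
        if t >= duration:
            raise InputError(f"event time {t} ms >= duration {duration} ms")
        data[index[ch], int(t // bin_width)] = 1
    return SpikeRaster(data, bin_width=bin_width, channel_ids=tuple(order))


def write_raster(raster: SpikeRaster, path: str | Path, format: str = "dense") -> None:
    """Write a raster to ``path`` in the ``dense`` or ``event-csv`` dialect.

    Output is deterministic for a fixed raster: dense rows follow channel
    order; event rows are sorted by (channel index, bin).
    """
    path = Path(path)
    if format == "dense":
        lines = [" ".join("1" if v else "0" for v in row) for row in raster.data]
        path.write_text("\n".join(lines) + "\n")
    elif format == "event-csv":
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["channel", "time_ms"])
            chans, bins = np.nonzero(raster.data)
            for n, t in zip(chans.tolist(), bins.tolist()):
                # event placed at the bin's left edge
                writer.writerow(
                    [raster.channel_ids[n], repr(raster.t0 + t * raster.bin_width)]
                )
    else:
        raise InputError(f"unknown raster format {format!r}")


def read_raster(
    path: str | Path,
    format: str = "dense",
    bin_width: float = 1.0,
    channel_order: Sequence[str] | None = None,
    duration: float | None = None,
) -> SpikeRaster:
    """Read a raster file.

    For ``dense``, every entry must be 0 or 1 and rows must have equal
    length.  For ``event-csv``, events are binned with :func:`bin_events`;
    ``channel_order`` defaults to the sorted set of observed channels and
    ``duration`` to one bin past the last event.
    """
    path = Path(path)
    if format == "dense":
        rows: list[list[int]] = []
        for ln, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            vals = []
            for tok in line.split():
                if tok not in ("0", "1"):
                    raise RasterFormatError(
                        f"{path}:{ln}: non-binary entry {tok!r} in dense raster"
                    )
                vals.append(int(tok))
            rows.append(vals)
        if not rows:
            raise RasterFormatError(f"{path}: empty dense raster file")
        widths = {len(r) for r in rows}
        if len(widths) != 1:
            raise RasterFormatError(f"{path}: ragged rows (widths {sorted(widths)})")
        return SpikeRaster(np.array(rows, dtype=np.uint8), bin_width=bin_width)
    elif format == "event-csv":
        records: list[tuple[str, float]] = []
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or [
                f.strip() for f in reader.fieldnames[:2]
            ] != ["channel", "time_ms"]:
                raise RasterFormatError(
                    f"{path}: expected header 'channel,time_ms', got {reader.fieldnames}"
                )
            for row in reader:
                try:
                    records.append((row["channel"], float(row["time_ms"])))
                except (TypeError, ValueError) as exc:
                    raise RasterFormatError(f"{path}: bad event row {row}") from exc
        events = EventList(tuple(records))
        if channel_order is None:
            channel_order = sorted(events.channels)
        if duration is None:
            last = max((t for _, t in events.records), default=0.0)
            duration = (np.floor(last / bin_width) + 1) * bin_width
        return bin_events(events, bin_width, channel_order, duration)
    raise InputError(f"unknown raster format {format!r}")
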