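"""Epoch-wise analysis of long recordings and cohort aggregation.

A long recording is analyzed in fixed-length epochs (the multielectrode-array
workflow uses 60 one-second epochs per recording).  Per-epoch lag tensors are
summed into one recording-level tensor before normalization, so a single PDF,
entropy and motif-class spectrum is reported per recording; this weights
epochs by their activity.  Per-epoch entropies are available as a diagnostic.

The chance-level reference repeats the same chain on surrogate recordings in
which each epoch's spikes are shuffled uniformly within that epoch
(preserving per-epoch spike counts).

Cohorts of recordings — multiple wells observed across days in vitro (DIV) —
are aggregated into a longitudinal table of box-whisker summaries per
(DIV, motif class); the median trace is only emitted where more than 7 wells
contribute (nonzero tensor total), mirroring the insufficient-activity
suppression used for sparse early-development recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .correlation import LagTensor, LagWindow, compute_triple_correlation
from .entropy import EntropyValue, estimate_pdf, shannon_entropy
from .errors import InputError
from .motifs import CLASS_LABELS, MotifSpectrum, motif_spectrum
from .raster import SpikeRaster
from .surrogate import generate_surrogate, normalized_prevalence

__all__ = [
    "EpochPlan",
    "CohortManifest",
    "RecordingReport",
    "analyze_recording",
    "aggregate_cohort",
]

MIN_WELLS_FOR_MEDIAN = 7  # median trace shown only if contributing wells > 7


@dataclass(frozen=True)
class EpochPlan:
    """Placement of analysis epochs within a recording.

    ``placement`` is one of ``"evenly_spaced"`` (first epoch at the start,
    last ending at the recording end, equal gaps), ``"contiguous"``
    (back-to-back from the start) or ``"listed"`` (explicit ``offsets_ms``).
    Epochs must lie within the recording and must not overlap.
    """

    epoch_length_ms: float = 1000.0
    n_epochs: int = 60
    placement: str = "evenly_spaced"
    offsets_ms: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.epoch_length_ms <= 0:
            raise InputError("epoch_length_ms must be positive")
        if self.placement not in ("evenly_spaced", "contiguous", "listed"):
            raise InputError(f"unknown epoch placement {self.placement!r}")
        if self.placement == "listed":
            if not self.offsets_ms:
                raise InputError("'listed' placement requires offsets_ms")
            object.__setattr__(self, "n_epochs", len(self.offsets_ms))
        elif self.n_epochs < 1:
            raise InputError("n_epochs must be >= 1")

    def epoch_bins(self, raster: SpikeRaster) -> list[tuple[int, int]]:
        """Epoch [start, stop) bin ranges for ``raster``; validates the plan."""
        length = int(round(self.epoch_length_ms / raster.bin_width))
        if length < 1:
            raise InputError("epoch shorter than one bin")
        total = raster.n_bins
        if self.placement == "listed":
            starts = [int(round(off / raster.bin_width)) for off in self.offsets_ms]
        elif self.placement == "contiguous":
            starts = [i * length for i in range(self.n_epochs)]
        else:
            span = total - length
            if span < 0:
                raise InputError(
                    f"recording ({total} bins) shorter than one epoch ({length} bins)"
                )
            if self.n_epochs == 1:
                starts = [0]
            else:
                starts = [
                    int(round(i * span / (self.n_epochs - 1)))
                    for i in range(self.n_epochs)
                ]
        ranges = [(s, s + length) for s in starts]
        for s, e in ranges:
            if s < 0 or e > total:
                raise InputError(
                    f"epoch [{s}, {e}) bins outside recording of {total} bins"
                )
        for (s0, e0), (s1, _) in zip(ranges, ranges[1:]):
            if s1 < e0:
                raise InputError("epochs overlap; reduce n_epochs or epoch length")
        return ranges


@dataclass(frozen=True)
class RecordingReport:
    """Per-recording analysis results (tensor summed over epochs)."""

    window: LagWindow
    plan: EpochPlan
    seed: int | None
    tensor: LagTensor
    spectrum: MotifSpectrum
    entropy: EntropyValue | None
    prevalence: np.ndarray | None  # M/mu - 1 per class, NaN where undefined
    mu: np.ndarray | None
    surrogate_entropy: dict[str, float] | None
    n_surrogates: int
    spike_count: int
    epoch_spike_counts: tuple[int, ...]
    epoch_tensor_totals: tuple[int, ...]
    silent_epochs: tuple[int, ...]
    epoch_entropies: tuple[float, ...] | None = None

    @property
    def contributing(self) -> bool:
        return int(self.tensor.total) > 0

    def to_dict(self) -> dict:
        """JSON-serializable summary (the 4D tensor itself is left out)."""
        return {
            "window": {"S": self.window.S, "T": self.window.T},
            "epoch_length_ms": self.plan.epoch_length_ms,
            "n_epochs": self.plan.n_epochs,
            "placement": self.plan.placement,
            "seed": self.seed,
            "n_surrogates": self.n_surrogates,
            "spike_count": self.spike_count,
            "tensor_total": int(self.tensor.total),
            "H_bits": None if self.entropy is None else self.entropy.H,
            "support_size": None if self.entropy is None else self.entropy.support_size,
            "spectrum": self.spectrum.as_dict(),
            "mu": None if self.mu is None else dict(zip(CLASS_LABELS, self.mu.tolist())),
            "prevalence": None
            if self.prevalence is None
            else {
                lab: (None if np.isnan(v) else v)
                for lab, v in zip(CLASS_LABELS, self.prevalence.tolist())
            },
            "surrogate_entropy": self.surrogate_entropy,
            "epoch_spike_counts": list(self.epoch_spike_counts),
            "epoch_tensor_totals": list(self.epoch_tensor_totals),
            "silent_epochs": list(self.silent_epochs),
            "epoch_entropies": None
            if self.epoch_entropies is None
            else list(self.epoch_entropies),
        }


def _epoch_tensors(
    epochs: Sequence[SpikeRaster], window: LagWindow
) -> list[LagTensor]:
    return [compute_triple_correlation(ep, window) for ep in epochs]


def _sum_tensors(tensors: Sequence[LagTensor], window: LagWindow) -> LagTensor:
    values = np.zeros(window.shape, dtype=np.int64)
    for t in tensors:
        values += t.values
    return LagTensor(
        values, window=window,
        source_spike_count=sum(t.source_spike_count for t in tensors),
    )


def analyze_recording(
    raster: SpikeRaster,
    window: LagWindow,
    plan: EpochPlan | None = None,
    n_surrogates: int = 100,
    seed: int | None = None,
    per_epoch_entropy: bool = False,
) -> RecordingReport:
    """Epoch a recording, run the full chain, and reference it to chance.

    Per-epoch lag tensors are computed independently (zero padding at epoch
    edges) and summed into one recording-level tensor; the PDF, entropy and
    motif spectrum are computed once from the sum.  Silent epochs are
    recorded in the report, not fatal.  With ``n_surrogates > 0`` the same
    chain runs on surrogate recordings (per-epoch uniform shuffles) to give
    the per-class chance expectation mu, the normalized prevalence
    ``M/mu - 1`` and the surrogate entropy distribution.
    """
    plan = plan or EpochPlan(epoch_length_ms=raster.duration, n_epochs=1,
                             placement="contiguous")
    ranges = plan.epoch_bins(raster)
    epochs = [raster.crop(s, e) for s, e in ranges]

    per_epoch = _epoch_tensors(epochs, window)
    totals = [int(t.total) for t in per_epoch]
    spike_counts = tuple(ep.spike_count for ep in epochs)
    tensor = _sum_tensors(per_epoch, window)
    spectrum = motif_spectrum(tensor)
    silent = tuple(i for i, c in enumerate(spike_counts) if c == 0)

    entropy = None
    if int(tensor.total) > 0:
        entropy = shannon_entropy(estimate_pdf(tensor))

    epoch_entropies = None
    if per_epoch_entropy:
        epoch_entropies = tuple(
            shannon_entropy(estimate_pdf(t)).H if tot > 0 else float("nan")
            for t, tot in zip(per_epoch, totals)
        )

    mu = prevalence = surr_summary = None
    if n_surrogates > 0 and int(tensor.total) > 0:
        rng = np.random.default_rng(seed)
        surr_M = np.zeros((n_surrogates, 14), dtype=float)
        surr_H = np.zeros(n_surrogates, dtype=float)
        for i in range(n_surrogates):
            shuffled = [generate_surrogate(ep, rng) for ep in epochs]
            st = _sum_tensors(_epoch_tensors(shuffled, window), window)
            surr_M[i] = motif_spectrum(st).M
            surr_H[i] = shannon_entropy(estimate_pdf(st)).H
        mu = surr_M.mean(axis=0)
        prevalence = normalized_prevalence(spectrum, mu=mu)
        surr_summary = {
            "mean": float(surr_H.mean()),
            "min": float(surr_H.min()),
            "q25": float(np.percentile(surr_H, 25)),
            "median": float(np.percentile(surr_H, 50)),
            "q75": float(np.percentile(surr_H, 75)),
            "max": float(surr_H.max()),
        }

    return RecordingReport(
        window=window,
        plan=plan,
        seed=seed,
        tensor=tensor,
        spectrum=spectrum,
        entropy=entropy,
        prevalence=prevalence,
        mu=mu,
        surrogate_entropy=surr_summary,
        n_surrogates=n_surrogates,
        spike_count=sum(spike_counts),
        epoch_spike_counts=spike_counts,
        epoch_tensor_totals=tuple(totals),
        silent_epochs=silent,
        epoch_entropies=epoch_entropies,
    )


@dataclass(frozen=True)
class CohortManifest:
    """Cohort description: one row per (well, DIV) recording.

    ``rows`` are ``(well_id, div, raster_path, bin_width)``; (well, DIV)
    pairs must be unique.
    """

    rows: tuple[tuple[str, int, str, float], ...]

    def __post_init__(self) -> None:
        keys = [(w, d) for w, d, _, _ in self.rows]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise InputError(f"duplicate (well, DIV) pairs in manifest: {dupes}")

    @property
    def divs(self) -> list[int]:
        return sorted({d for _, d, _, _ in self.rows})

    @property
    def wells(self) -> list[str]:
        return sorted({w for w, _, _, _ in self.rows})


def aggregate_cohort(
    reports: dict[tuple[str, int], RecordingReport],
    manifest: CohortManifest | None = None,
) -> pd.DataFrame:
    """Longitudinal box-whisker table across wells per (DIV, metric, class).

    For every DIV and every motif class, the 25th/50th/75th percentiles and
    the range of the per-well values are tabulated over *contributing* wells
    (nonzero tensor total).  ``median_shown`` is True only when more than
    7 wells contribute (strictly greater); otherwise the median trace is
    suppressed for insufficient spike activity.  Metrics: per-class
    prevalence ``M``, normalized prevalence ``M_over_mu_minus_1``, plus the
    recording-level ``H_bits`` and ``spike_count``.
    """
    if manifest is not None:
        listed = {(w, d) for w, d, _, _ in manifest.rows}
        extra = set(reports) - listed
        if extra:
            raise InputError(f"reports not in manifest: {sorted(extra)}")
    if not reports:
        raise InputError("no reports to aggregate")
    windows = {r.window for r in reports.values()}
    if len(windows) > 1:
        raise InputError(f"reports mix lag windows: {windows}")

    divs = sorted({d for _, d in reports})
    records = []
    for div in divs:
        at_div = {w: r for (w, d), r in reports.items() if d == div}
        contributing = {w: r for w, r in at_div.items() if r.contributing}
        n_con = len(contributing)

        def summarize(metric: str, class_label: str | None, vals: np.ndarray) -> None:
            vals = vals[np.isfinite(vals)]
            rec = {
                "div": div,
                "metric": metric,
                "class_label": class_label,
                "n_wells": len(at_div),
                "n_contributing": n_con,
                "median_shown": n_con > MIN_WELLS_FOR_MEDIAN,
            }
            if vals.size:
                rec.update(
                    lo=float(vals.min()),
                    q25=float(np.percentile(vals, 25)),
                    median=float(np.percentile(vals, 50)),
                    q75=float(np.percentile(vals, 75)),
                    hi=float(vals.max()),
                )
            else:
                rec.update(lo=np.nan, q25=np.nan, median=np.nan, q75=np.nan, hi=np.nan)
            records.append(rec)

        for i, lab in enumerate(CLASS_LABELS):
            summarize("M", lab, np.array([float(r.spectrum.M[i]) for r in contributing.values()]))
            if all(r.prevalence is not None for r in contributing.values()):
                summarize(
                    "M_over_mu_minus_1",
                    lab,
                    np.array([float(r.prevalence[i]) for r in contributing.values()]),
                )
        summarize(
            "H_bits",
            None,
            np.array([r.entropy.H for r in contributing.values() if r.entropy]),
        )
        summarize(
            "spike_count", None, np.array([float(r.spike_count) for r in at_div.values()])
        )
    return pd.DataFrame.from_records(records)
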