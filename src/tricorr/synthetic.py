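"""Synthetic raster generators for validation and testing.

Two generators cover the needs of the method's worked example and its
property tests:

* :func:`generate_feedforward_raster` plants isolated three-spike
  feedforward motifs (class XIII) far enough apart that every
  triple-correlation contribution involves spikes of a single motif.  With
  the default template and 16 motifs this reproduces the worked example:
  48 spikes, zero-lag tensor value 48, and 16 contributions in each of the
  three distinct pairwise-lag cells of the (n2, t2) = (0, 0) slice.
* :func:`generate_random_raster` draws i.i.d. Bernoulli cells, the null
  input for property tests.

Both are reproducible from a :class:`numpy.random.Generator`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError, PlacementError
from .raster import SpikeRaster

__all__ = [
    "MotifTemplate",
    "DEFAULT_FEEDFORWARD_TEMPLATE",
    "generate_feedforward_raster",
    "generate_random_raster",
]


@dataclass(frozen=True)
class MotifTemplate:
    """Three spatiotemporal offsets (channel, bin) defining one motif.

    The reference spike sits at offset (0, 0).  For the worked example's
    equal-count property the three pairwise lag vectors must be pairwise
    distinct even after sign flips, so that each within-motif spike pair
    occupies its own pairwise-lag cell.
    """

    offsets: tuple[tuple[int, int], ...] = ((0, 0), (1, 1), (2, 3))

    def __post_init__(self) -> None:
        if len(self.offsets) != 3:
            raise InputError("a motif template needs exactly three offsets")
        if len(set(self.offsets)) != 3:
            raise InputError("motif offsets must be distinct points")

    @property
    def pairwise_lags(self) -> list[tuple[int, int]]:
        """The three (channel, bin) lag vectors between ordered spike pairs."""
        (a, b, c) = self.offsets
        return [
            (b[0] - a[0], b[1] - a[1]),
            (c[0] - a[0], c[1] - a[1]),
            (c[0] - b[0], c[1] - b[1]),
        ]

    @property
    def has_distinct_pairwise_lags(self) -> bool:
        """True iff the six signed pairwise lag vectors are all distinct."""
        signed = set()
        for dn, dt in self.pairwise_lags:
            signed.add((dn, dt))
            signed.add((-dn, -dt))
        return len(signed) == 6

    @property
    def channel_extent(self) -> int:
        chans = [c for c, _ in self.offsets]
        return max(chans) - min(chans)

    @property
    def bin_extent(self) -> int:
        bins = [t for _, t in self.offsets]
        return max(bins) - min(bins)


DEFAULT_FEEDFORWARD_TEMPLATE = MotifTemplate()


def generate_feedforward_raster(
    n_motifs: int = 16,
    template: MotifTemplate = DEFAULT_FEEDFORWARD_TEMPLATE,
    shape: tuple[int, int] = (25, 120),
    margin: tuple[int, int] = (5, 4),
    rng: np.random.Generator | None = None,
    bin_width: float = 1.0,
    max_attempts_per_motif: int = 2000,
) -> SpikeRaster:
    """Raster of ``n_motifs`` isolated copies of ``template``.

    Placement is random with rejection, seeded by ``rng``.  Two constraints
    are enforced so that a lag window of ``margin = (S, T)`` sees only
    within-motif triplets:

    * every spike lies at least S channels / T bins from every raster edge
      (so within-motif contributions are never truncated);
    * every pair of spikes from *different* motifs is separated by more
      than S channels or more than T bins.

    The second constraint is sufficient for full isolation: a cross-motif
    contribution would need a reference spike within the window of spikes
    from two motifs, and whichever of those two factor pairs crosses motifs
    is itself a cross-motif spike pair inside the window — excluded.

    Raises
    ------
    PlacementError
        If ``n_motifs`` motifs cannot be placed under the isolation
        constraints within the attempt budget.
    """
    rng = np.random.default_rng() if rng is None else rng
    N, L = shape
    S, T = margin
    ech, ebin = template.channel_extent, template.bin_extent
    min_off_ch = min(c for c, _ in template.offsets)
    min_off_bin = min(t for _, t in template.offsets)

    lo_ch, hi_ch = S - min_off_ch, N - 1 - S - (min_off_ch + ech)
    lo_bin, hi_bin = T - min_off_bin, L - 1 - T - (min_off_bin + ebin)
    if n_motifs > 0 and (hi_ch < lo_ch or hi_bin < lo_bin):
        raise PlacementError(
            f"shape {shape} too small for template extent ({ech}, {ebin}) "
            f"with margin (S={S}, T={T})"
        )

    spikes: list[tuple[int, int]] = []  # all spikes of already-placed motifs
    placed: list[tuple[int, int]] = []
    for _ in range(n_motifs):
        for _attempt in range(max_attempts_per_motif):
            c = int(rng.integers(lo_ch, hi_ch + 1))
            b = int(rng.integers(lo_bin, hi_bin + 1))
            new = [(c + dc, b + db) for dc, db in template.offsets]
            if all(
                abs(nc - pc) > S or abs(nb - pb) > T
                for nc, nb in new
                for pc, pb in spikes
            ):
                placed.append((c, b))
                spikes.extend(new)
                break
        else:
            raise PlacementError(
                f"could not place motif {len(placed) + 1} of {n_motifs} in a "
                f"{N}x{L} raster after {max_attempts_per_motif} attempts; "
                "enlarge the raster or reduce n_motifs"
            )

    data = np.zeros((N, L), dtype=np.uint8)
    for sc, sb in spikes:
        data[sc, sb] = 1
    return SpikeRaster(data, bin_width=bin_width)


def generate_random_raster(
    shape: tuple[int, int],
    p: float,
    rng: np.random.Generator | None = None,
    bin_width: float = 1.0,
) -> SpikeRaster:
    """I.i.d. Bernoulli(p) raster; expected spike count is p * N * n_bins."""
    if not 0 <= p <= 1:
        raise InputError(f"spike probability must be in [0, 1], got {p}")
    rng = np.random.default_rng() if rng is None else rng
    data = (rng.random(shape) < p).astype(np.uint8)
    return SpikeRaster(data, bin_width=bin_width)
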