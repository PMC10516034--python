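# Methods

## Model and computation

The package analyzes a binary spike raster `r(n, t)` — channels × time bins,
entry 1 if the channel fired at least once in the bin. Time bins are
half-open `[t·Δ, (t+1)·Δ)`; multiple events per bin clip to 1, since every
downstream quantity is defined on binary rasters. How multi-unit activity or
duplicate events should be treated is an acquisition-side question; clipping
is this package's convention and is applied identically everywhere.

The triple correlation over a lag window (max spatial lag S, max temporal
lag T) is accumulated as raw sums over all reference cells,

    c3(n1,t1,n2,t2) = Σ_{n,t} r(n,t) r(n+n1,t+t1) r(n+n2,t+t2),

with zero padding: out-of-range factors are 0 and every raster cell is a
reference position. Two properties motivated choosing sums plus padding over
the alternatives (averaging over reference positions; restricting references
to the interior):

* the zero-lag cell then equals the spike count exactly, which anchors the
  worked example and gives the class-0 "spike rate" reading of the spectrum;
* averaging is a constant factor and cancels in the PDF and the entropy, so
  nothing downstream depends on the choice. `average=True` and
  `boundary="valid"` expose the alternatives.

The production path iterates over spikes, not cells: for each reference
spike the ±S × ±T binary patch around it is gathered and the patch outer
product accumulated (integer matrix product over spike chunks). This is an
exact reorganization of the sum — bit-identical to the nested-loop oracle
kept in `brute_force_oracle`, which the test suite compares against on
random rasters — at O(spikes · ((2S+1)(2T+1))²) cost. Memory for the
accumulator is ((2S+1)(2T+1))² int64, which bounds the practical window
size; the 11×9 worked-example window needs ~0.8 MB.

## Configurations and the 14 motif classes

A nonzero contribution involves the reference node (0,0) and nodes at
(n1,t1), (n2,t2). Its *configuration* is the pair of weak orders — of the
three times (0, t1, t2) and of the three channels (0, n1, n2). Thirteen weak
orders of three labelled items exist per axis, giving 169 configurations,
all realizable (node overlap included: auto- and cross-correlation terms).

The collapse of 169 configurations into 14 classes keeps temporal direction
(divergence XI vs convergence XII) but treats channel labels as fully
arbitrary — the spatial ordering of channels in a raster carries no meaning,
so only the *co-occurrence partition* (which nodes share a channel) enters.
A class is therefore determined by:

1. how many distinct spatiotemporal points the three nodes occupy;
2. which nodes share a channel;
3. the temporal order of the nodes, direction preserved.

Enumerating those invariants yields exactly 14 classes:

| class | structure | sizes (of 169) |
|---|---|---|
| 0 | all three nodes coincide | 1 |
| I | two points, one channel (autocorrelation) | 6 |
| II | three points, one channel, three times | 6 |
| III | two points, one time (synchrony) | 6 |
| IV | three channels, one time (triplet synchrony) | 6 |
| V | two points, different channel and time (cross-correlation) | 12 |
| VI | two channels, two times; single node early | 12 |
| VII | two channels, two times; single node late | 12 |
| VIII | two channels, three times; lone-channel node first | 12 |
| IX | two channels, three times; lone-channel node middle (feedback a→b→a) | 12 |
| X | two channels, three times; lone-channel node last | 12 |
| XI | three channels, two times; single node early (divergence) | 18 |
| XII | three channels, two times; single node late (convergence) | 18 |
| XIII | three channels, three times (feedforward) | 36 |

Design notes. A stricter collapse that keeps spatial weak order up to
reflection only (rather than full channel relabelling) yields 19 classes,
not 14, so relabel-invariance is the collapse that produces the canonical
count. The named classes (0, I, III–V, IX, XI–XIII) are pinned by their
structural definitions; among the unnamed ones, which of the two L-shaped
orientations is VI vs VII, and which lone-extreme pattern is VIII vs X, is a
labelling convention — chosen here as single-node-early → lower numeral, by
analogy with XI (divergence) preceding XII (convergence). No numeric output
depends on that convention. Classes VI and VII are exactly the three-point
motifs whose node pairs realize classes I, III and V simultaneously, which
is why their chance expectation is conditioned on those lower-order classes.

The mapping ships as a 169-row CSV (`data/motif_classes.csv`). At load it is
validated against the partition invariants (169 unique configurations, 14
classes, class 0 a singleton), the anchor predicates above, and the
structural rule itself; classification is a table lookup keyed by the two
rank codes. The test suite additionally checks magnitude-invariance,
node-relabelling consistency (any of the three nodes may serve as reference)
and spatial-reflection invariance by exhaustive sweep.

## PDF and entropy

The 4D lag PDF is the maximum-likelihood histogram normalization
`p = c3 / Σ c3` over the full window — no smoothing, no pseudocounts, no
support trimming (structurally impossible cells simply hold 0 and contribute
nothing via 0·log 0 := 0). Entropy is the plug-in estimate in bits
(`base=e` optional, never default); no bias correction (Miller–Madow, NSB)
is applied. An all-zero tensor (empty raster) raises a degenerate-input
error rather than producing NaN. The PDF sum is checked to 1e−12; the
entropy of a one-cell PDF is clamped to exactly 0 against round-off.

## Surrogates

The chance reference is the spike-rate-matched full shuffle: spike positions
resampled uniformly without replacement over all N·T cells, preserving shape,
binariness and spike count, destroying all spatiotemporal structure. The
per-class surrogate mean μ feeds M/μ − 1; classes with μ = 0 report NaN (an
undefined marker), never infinity, and `normalized_prevalence(..., mu=...)`
is the hook for analytic chance expectations. One named RNG drives each
ensemble; the seed is recorded in every output. Jitter or ISI-preserving
surrogates are out of scope: the reference model here is rate-matched noise.

## Synthetic generators

`generate_feedforward_raster` plants `n_motifs` copies of a three-spike
template (default offsets (0,0), (1,1), (2,3): three distinct channels,
strictly increasing times). The default template's three pairwise lag
vectors (1,1), (2,3), (1,2) stay distinct after sign flips, so each
within-motif spike pair occupies its own pairwise-lag cell — with 16 motifs,
16 contributions per cell rather than a 32/16 split, which an equal-step
chain like (0,0),(1,1),(2,2) would produce.

Placement is random with rejection under two constraints relative to the
margin (S, T) (default (5, 4), the worked-example window): every spike at
least S channels / T bins from every raster edge (within-motif triplets are
never truncated, giving the mirror-symmetric pairwise slice), and every
cross-motif spike pair separated by more than S channels or more than T
bins. The second constraint alone guarantees full isolation: a cross-motif
contribution would need a reference spike with two factor spikes from
different motifs inside its window, and whichever factor pair crosses motifs
is then itself a cross-motif spike pair within (S, T) — excluded. The
spectrum support of the fixture being exactly {0, V, XIII} certifies this in
the tests. Failure to place within the attempt budget raises a deterministic
placement error, never silent overlap.

The default shape (25 channels × 120 bins, 48 spikes ≈ 1.6% occupancy) is
the compact-raster regime the worked example illustrates. Density matters
for the entropy comparison: in a very dilute raster a uniform shuffle
scatters spikes so far apart that almost the only surviving contribution is
the zero-lag cell, collapsing surrogate entropy below the raster's and
inverting the intended comparison. At the default geometry the surrogate
ensemble's minimum entropy exceeds the fixture's by ≈1 bit across seeds.

What the generators emulate — and what they do not: isolated stereotyped
motifs and i.i.d. Bernoulli noise. Real recordings have refractoriness,
bursts, rate nonstationarity, overlapping motifs and correlated noise; tests
passing on these fixtures validate the computation chain, not robustness to
those features.

## Epoch pipeline and cohorts

Long recordings are analyzed in fixed-length epochs (defaults: 60 epochs of
1000 ms, evenly spaced; contiguous or explicitly listed placements are
available, and the placement is recorded in the report since results can
depend on it). Per-epoch tensors are summed into one recording-level tensor
*before* normalization, yielding one PDF, one entropy and one spectrum per
recording; this weights epochs by their activity. Per-epoch entropies are
available as a diagnostic (`per_epoch_entropy=True`). Epoch tensors use zero
padding at epoch edges, so when epoch boundaries have silent margins wider
than T the summed tensor equals that of the concatenated recording
(additivity, tested). Silent epochs are recorded, not fatal. Surrogate
recordings shuffle each epoch's spikes within that epoch, preserving the
per-epoch spike counts, and run through the identical sum-then-normalize
chain.

Cohort aggregation tabulates, per (day in vitro, motif class), the
25th/50th/75th percentiles and range across wells of M, M/μ − 1, entropy and
spike count. A well *contributes* at a DIV if its tensor total is nonzero;
the median trace is marked shown only when contributing wells exceed 7
(strictly), the suppression rule for insufficient activity. Temporal lags
are configured in ms and converted to bins via the bin width (−50..50 ms at
1 ms bins ≡ T = 50).

## Problem sizes

The shipped analyses run at desk scale: the 25×120 fixture with the 11×9 lag
window, surrogate ensembles of 100, oracle cross-checks on rasters up to
8×20 with S, T ≤ 2, and synthetic cohorts of 8–12 wells with 10–15
surrogates per recording. Full MEA-scale windows (64 channels, ±50 ms) are
supported by the same code paths but scale as spikes · window⁴ in time and
window⁴ in memory for the accumulator.

## Known limitations

* The plug-in entropy is biased low for sparse tensors; comparisons should
  be made at matched spike counts (the surrogate ensemble does exactly
  this).
* The empirical μ is a Monte-Carlo estimate; with few iterations rare
  classes can have μ = 0 (reported as NaN prevalence).
* The classifier's unnamed-class labelling convention (VI/VII, VIII/X) is
  internal; cross-study comparison of those specific labels should verify
  the convention first.
* Channel order is treated as arbitrary, which suits electrode arrays
  without meaningful linear geometry; data with a meaningful spatial axis
  (e.g. laminar probes) would discard that structure.
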