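"""Three-node motif configurations and the 14 motif classes.

A nonzero triple-correlation contribution at lag quadruple ``(n1, t1, n2, t2)``
involves three nodes: the reference at ``(0, 0)`` and two nodes at
``(n1, t1)`` and ``(n2, t2)``.  Only the qualitative shape of the triplet
matters for classification, captured by the pair

* the weak order of the three node times ``(0, t1, t2)`` — 13 shapes, and
* the weak order of the three node channels ``(0, n1, n2)`` — 13 shapes,

giving 169 distinct *configurations*, including those in which nodes overlap
(as in auto- and cross-correlation).  The configurations collapse into 14
qualitatively distinct *motif classes* 0–XIII.  The collapse keeps temporal
direction (divergence and convergence are distinct classes) but treats the
channel labelling as arbitrary: a class is determined by which nodes share a
channel, not by where those channels sit relative to one another.  Classes
embody familiar neuronal processing properties: spike rate (0),
autocorrelation (I), synchrony (III–IV), cross-correlation (V), feedback
(IX), divergence (XI), convergence (XII) and feedforward (XIII).

The configuration→class mapping ships as a 169-row CSV
(``data/motif_classes.csv``); it is validated at load against the partition
invariants and the anchor predicates of the named classes.

Summing the lag-tensor cells that classify to each class yields the
*motif-class spectrum*, the per-class prevalence ``M`` used in the
chance-normalized measure ``M/mu - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np

from .correlation import LagTensor, LagWindow
from .errors import InputError, TricorrError

__all__ = [
    "CLASS_LABELS",
    "Configuration",
    "MotifClass",
    "MotifSpectrum",
    "classify_lag_quadruple",
    "enumerate_configurations",
    "motif_spectrum",
]

CLASS_LABELS: tuple[str, ...] = (
    "0", "I", "II", "III", "IV", "V", "VI",
    "VII", "VIII", "IX", "X", "XI", "XII", "XIII",
)

CLASS_DESCRIPTIONS: dict[str, str] = {
    "0": "spike rate (all three nodes coincide)",
    "I": "autocorrelation (two nodes on one channel at two times)",
    "II": "triplet autocorrelation (three nodes on one channel at three times)",
    "III": "pairwise synchrony (two channels at one time)",
    "IV": "triplet synchrony (three channels at one time)",
    "V": "cross-correlation (two nodes differing in channel and time)",
    "VI": "single node then a synchronous pair, on two channels",
    "VII": "synchronous pair then a single node, on two channels",
    "VIII": "single node on one channel then a doublet on another",
    "IX": "feedback (a-b-a: third node returns to the first channel)",
    "X": "doublet on one channel then a single node on another",
    "XI": "divergence (one node then a synchronous pair on two other channels)",
    "XII": "convergence (a synchronous pair then a node on a third channel)",
    "XIII": "feedforward (three channels in sequence at three times)",
}


@dataclass(frozen=True)
class MotifClass:
    """One of the 14 motif classes, labelled 0–XIII."""

    label: str
    description: str = ""

    def __post_init__(self) -> None:
        if self.label not in CLASS_LABELS:
            raise InputError(f"unknown motif class label {self.label!r}")
        if not self.description:
            object.__setattr__(self, "description", CLASS_DESCRIPTIONS[self.label])

    @property
    def index(self) -> int:
        return CLASS_LABELS.index(self.label)


@dataclass(frozen=True)
class Configuration:
    """A three-node configuration: (temporal weak order, spatial weak order).

    Order codes are dense-rank strings over (reference, node 1, node 2);
    e.g. ``"011"`` means the reference is earliest and the two other nodes
    tie later, ``"000"`` means all three coincide on that axis.
    """

    id: int
    temporal_order: str
    spatial_order: str
    class_label: str


def _rank_code(a: int, b: int, c: int) -> str:
    """Dense-rank string of a value triple, e.g. (3, 3, 7) -> '001'."""
    levels = sorted({a, b, c})
    return "".join(str(levels.index(v)) for v in (a, b, c))


def _all_order_codes() -> list[str]:
    codes = {_rank_code(a, b, c) for a in range(3) for b in range(3) for c in range(3)}
    return sorted(codes)


def _class_from_lags(n1: int, t1: int, n2: int, t2: int) -> str:
    """Motif class of a lag quadruple, derived from the triplet's structure.

    The three nodes are A=(0,0), B=(n1,t1), C=(n2,t2).  The class depends
    only on (i) how many distinct spatiotemporal points they occupy, (ii)
    which nodes share a channel, and (iii) the temporal order of the nodes
    (direction preserved).
    """
    eq_ab = n1 == 0 and t1 == 0
    eq_ac = n2 == 0 and t2 == 0
    eq_bc = n1 == n2 and t1 == t2

    if eq_ab and eq_ac:
        return "0"

    if eq_ab or eq_ac or eq_bc:
        # exactly two distinct points; (dn, dt) is their lag vector
        dn, dt = (n2, t2) if eq_ab else (n1, t1)
        if dn == 0:
            return "I"
        if dt == 0:
            return "III"
        return "V"

    channels = (0, n1, n2)
    times = (0, t1, t2)
    u = len(set(channels))
    v = len(set(times))
    if u == 1:
        return "II"
    if v == 1:
        return "IV"
    if u == 3 and v == 3:
        return "XIII"
    if v == 2:
        # one time value holds a synchronous pair, the other a single node
        t_single = next(t for t in set(times) if times.count(t) == 1)
        t_pair = next(t for t in set(times) if times.count(t) == 2)
        single_early = t_single < t_pair
        if u == 2:
            return "VI" if single_early else "VII"
        return "XI" if single_early else "XII"
    # u == 2, v == 3: one channel holds two nodes, the other one node
    ch_single = next(ch for ch in set(channels) if channels.count(ch) == 1)
    t_lone = times[channels.index(ch_single)]
    rank = sorted(times).index(t_lone)
    return ("VIII", "IX", "X")[rank]


def _representative_lags(temporal_order: str, spatial_order: str) -> tuple[int, int, int, int]:
    """A lag quadruple realizing the given configuration (ranks as values)."""
    td = [int(d) for d in temporal_order]
    sd = [int(d) for d in spatial_order]
    return sd[1] - sd[0], td[1] - td[0], sd[2] - sd[0], td[2] - td[0]


def _generate_table() -> list[Configuration]:
    """The full 169-row configuration table derived from the collapse rule."""
    rows = []
    codes = _all_order_codes()
    cid = 0
    for t_code in codes:
        for s_code in codes:
            cid += 1
            n1, t1, n2, t2 = _representative_lags(t_code, s_code)
            rows.append(Configuration(cid, t_code, s_code, _class_from_lags(n1, t1, n2, t2)))
    return rows


def _validate_table(rows: list[Configuration]) -> None:
    """Partition invariants plus anchor predicates for the named classes."""
    if len(rows) != 169:
        raise TricorrError(f"configuration table has {len(rows)} rows, expected 169")
    keys = {(r.temporal_order, r.spatial_order) for r in rows}
    if len(keys) != 169:
        raise TricorrError("configuration table has duplicate (temporal, spatial) keys")
    codes = set(_all_order_codes())
    for r in rows:
        if r.temporal_order not in codes or r.spatial_order not in codes:
            raise TricorrError(f"configuration {r.id} has invalid order codes")
        if r.class_label not in CLASS_LABELS:
            raise TricorrError(f"configuration {r.id} has unknown class {r.class_label!r}")
    labels = {r.class_label for r in rows}
    if labels != set(CLASS_LABELS):
        raise TricorrError(f"table covers {len(labels)} classes, expected all 14")
    by_key = {(r.temporal_order, r.spatial_order): r.class_label for r in rows}
    # anchors pinned by the class definitions
    if by_key[("000", "000")] != "0":
        raise TricorrError("all-coincident configuration must be class 0")
    if sum(1 for r in rows if r.class_label == "0") != 1:
        raise TricorrError("class 0 must contain exactly one configuration")
    anchors = [
        ((0, 2, 0, 0), "I"),    # one channel, two times
        ((1, 0, 0, 0), "III"),  # two channels, one time
        ((2, 3, 0, 0), "V"),    # two nodes apart in channel and time
        ((0, 1, 0, 2), "II"),   # one channel, three times
        ((1, 0, 2, 0), "IV"),   # three channels, one time
        ((1, 1, 0, 2), "IX"),   # a -> b -> a feedback
        ((1, 1, 2, 1), "XI"),   # reference, then synchronous pair
        ((1, -1, 2, -1), "XII"),  # synchronous pair, then reference
        ((1, 1, 2, 3), "XIII"),  # monotone feedforward chain
    ]
    for (n1, t1, n2, t2), expect in anchors:
        got = by_key[(_rank_code(0, t1, t2), _rank_code(0, n1, n2))]
        if got != expect:
            raise TricorrError(
                f"anchor ({n1},{t1},{n2},{t2}) classifies to {got}, expected {expect}"
            )
    # the collapse rule itself must reproduce every row
    for r in rows:
        derived = _class_from_lags(*_representative_lags(r.temporal_order, r.spatial_order))
        if derived != r.class_label:
            raise TricorrError(
                f"configuration {r.id} ({r.temporal_order}, {r.spatial_order}): "
                f"table says {r.class_label}, structural rule says {derived}"
            )


@lru_cache(maxsize=1)
def _load_table() -> tuple[Configuration, ...]:
    path = resources.files("tricorr").joinpath("data/motif_classes.csv")
    rows: list[Configuration] = []
    lines = path.read_text().splitlines()
    if lines[0].strip() != "config_id,temporal_order_code,spatial_order_code,class_label":
        raise TricorrError("motif_classes.csv: unexpected header")
    for line in lines[1:]:
        cid, t_code, s_code, label = line.strip().split(",")
        rows.append(Configuration(int(cid), t_code, s_code, label))
    _validate_table(rows)
    return tuple(rows)


@lru_cache(maxsize=1)
def _table_index() -> dict[tuple[str, str], Configuration]:
    return {(r.temporal_order, r.spatial_order): r for r in _load_table()}


def enumerate_configurations() -> list[Configuration]:
    """All 169 three-node configurations with their class assignments."""
    return list(_load_table())


def classify_lag_quadruple(n1: int, t1: int, n2: int, t2: int) -> tuple[Configuration, MotifClass]:
    """Configuration and motif class of one lag quadruple.

    Total and deterministic on all integer quadruples; only the sign and
    tie structure of the lags is used, so e.g. (1,1,2,3) and (4,2,7,9)
    share a configuration.
    """
    config = _table_index()[(_rank_code(0, t1, t2), _rank_code(0, n1, n2))]
    return config, MotifClass(config.class_label)


@lru_cache(maxsize=8)
def _class_index_grid(S: int, T: int) -> np.ndarray:
    """Per-cell class index (0..13) for every lag quadruple in the window."""
    idx = {(r.temporal_order, r.spatial_order): CLASS_LABELS.index(r.class_label)
           for r in _load_table()}
    grid = np.empty((2 * S + 1, 2 * T + 1, 2 * S + 1, 2 * T + 1), dtype=np.int8)
    for n1 in range(-S, S + 1):
        for t1 in range(-T, T + 1):
            s_part = {}
            for n2 in range(-S, S + 1):
                s_code = s_part.get(n2)
                if s_code is None:
                    s_code = s_part[n2] = _rank_code(0, n1, n2)
                for t2 in range(-T, T + 1):
                    grid[n1 + S, t1 + T, n2 + S, t2 + T] = idx[
                        (_rank_code(0, t1, t2), s_code)
                    ]
    return grid


@dataclass(frozen=True)
class MotifSpectrum:
    """Summed triple-correlation contribution per motif class (0–XIII).

    ``M[i]`` is the total over all lag-tensor cells classifying to class
    ``CLASS_LABELS[i]``; the class totals conserve the tensor total.
    """

    M: np.ndarray
    window: LagWindow
    spike_count: int = 0

    def __post_init__(self) -> None:
        m = np.asarray(self.M)
        if m.shape != (14,):
            raise InputError(f"spectrum must have 14 entries, got shape {m.shape}")
        object.__setattr__(self, "M", m)

    def __getitem__(self, label: str):
        return self.M[CLASS_LABELS.index(label)]

    @property
    def total(self):
        return self.M.sum()

    def as_dict(self) -> dict[str, float]:
        return {lab: self.M[i].item() for i, lab in enumerate(CLASS_LABELS)}


def motif_spectrum(tensor: LagTensor) -> MotifSpectrum:
    """Collapse a lag tensor onto the 14 motif classes.

    Conservation: the class sums add up to the tensor total exactly.
    """
    grid = _class_index_grid(tensor.window.S, tensor.window.T)
    flat = tensor.values.ravel()
    labels = grid.ravel()
    M = np.zeros(14, dtype=flat.dtype)
    np.add.at(M, labels, flat)
    return MotifSpectrum(M, window=tensor.window, spike_count=tensor.source_spike_count)
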