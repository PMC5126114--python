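"""Acoustic networks: binned cross-correlation synchrony and Markov turn-taking.

Two complementary undirected bird-by-bird networks:

* **Cross-correlation** — time is split into 500 ms bins and each bird
  gets a binary signal (1 if it vocalized in the bin).  The edge weight of
  a dyad is the zero-lag Pearson correlation of the two binary signals
  (population standard deviations), which is independent of the total
  number of vocalizations.

* **Turn-taking** — the recording's vocalizations are reduced to the
  sequence of caller identities; a first-order Markov transition matrix is
  estimated by pair counting, and the dyad edge weight is
  ``max(p(i->j), p(j->i))``.  Self-transitions remain in the matrix but
  never contribute to dyad edges.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .session_io import EventTable

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH_S = 0.5

WEIGHT_CC = "cross_correlation"
WEIGHT_MAX_TRANSITION = "max_transition"


@dataclass
class BinarySignal:
    """Per-bird binned vocal presence: bit b is 1 iff the bird vocalized in bin b."""

    bird_id: str
    bits: np.ndarray
    bin_width_s: float = DEFAULT_BIN_WIDTH_S

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.int8)
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("bits must be 0/1")
        if self.bin_width_s <= 0:
            raise ValueError("bin width must be positive")

    @property
    def n_bins(self) -> int:
        return len(self.bits)


def binarize(
    table: EventTable,
    bird_id: str,
    duration_s: float,
    bin_width_s: float = DEFAULT_BIN_WIDTH_S,
    onset_only: bool = False,
) -> BinarySignal:
    """Binary presence signal for one bird over ``ceil(duration / bin_width)`` bins.

    By default an event sets every bin it overlaps; with ``onset_only``
    only the bin containing its onset.
    """
    if bin_width_s <= 0:
        raise ValueError("bin width must be positive")
    n_bins = math.ceil(duration_s / bin_width_s)
    bits = np.zeros(n_bins, dtype=np.int8)
    sub = table.df[table.df["bird_id"] == bird_id]
    for start, end in zip(sub["start_s"], sub["end_s"]):
        b0 = int(start // bin_width_s)
        if onset_only:
            b1 = b0
        else:
            b1 = max(b0, math.ceil(end / bin_width_s) - 1)  # end is exclusive
        bits[max(b0, 0) : min(b1, n_bins - 1) + 1] = 1
    return BinarySignal(bird_id, bits, bin_width_s)


def cross_correlation(s1: BinarySignal, s2: BinarySignal) -> float:
    """Zero-lag Pearson correlation of two binary signals.

    ``mean[(S1 - mean S1)(S2 - mean S2)] / (std(S1) * std(S2))`` with
    population (divide-by-n) standard deviations.  Returns NaN (undefined)
    when either signal has zero variance (all-silent or all-active bird).
    """
    if s1.n_bins != s2.n_bins:
        raise ValueError(f"signals differ in length: {s1.n_bins} vs {s2.n_bins}")
    a = s1.bits.astype(float)
    b = s2.bits.astype(float)
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return float("nan")
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def caller_sequence(table: EventTable) -> list[str]:
    """Caller identities in onset order.

    Simultaneous onsets are ordered by (end_s, bird_id) — deterministic
    and logged.
    """
    if len(table) == 0:
        return []
    df = table.df
    dup = df["start_s"].duplicated(keep=False)
    if dup.any():
        logger.info("%d events share an onset; tie order is (end_s, bird_id)", int(dup.sum()))
    # EventTable already sorts by (start_s, end_s, bird_id)
    return df["bird_id"].tolist()


@dataclass
class TransitionMatrix:
    """First-order Markov matrix over caller identities.

    ``counts[i, j]`` is how often bird ``j`` called immediately after bird
    ``i``; ``probs`` are row-normalized, with all-NaN rows for birds that
    never precede another call (flagged in ``undefined_rows``).
    """

    birds: tuple[str, ...]
    counts: np.ndarray
    probs: np.ndarray = field(init=False)
    undefined_rows: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.birds)
        if self.counts.shape != (n, n):
            raise ValueError("counts shape does not match bird list")
        if (self.counts < 0).any():
            raise ValueError("negative transition counts")
        row_sums = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            probs = self.counts / row_sums[:, None]
        probs[row_sums == 0] = np.nan
        self.probs = probs
        self.undefined_rows = tuple(b for b, s in zip(self.birds, row_sums) if s == 0)

    def prob(self, i: str, j: str) -> float:
        return float(self.probs[self.birds.index(i), self.birds.index(j)])

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        idx = list(self.birds)
        return (
            pd.DataFrame(self.counts, index=idx, columns=idx),
            pd.DataFrame(self.probs, index=idx, columns=idx),
        )


def estimate_transition_matrix(seq: list[str], birds: tuple[str, ...] | list[str]) -> TransitionMatrix:
    """Pair-count the caller sequence into a transition matrix.

    Counts total ``len(seq) - 1``; the marginal call counts of every bird
    (except sequence endpoints) are recoverable from the count matrix.  A
    sequence shorter than 2 yields an all-undefined matrix with a warning.
    """
    birds = tuple(birds)
    index = {b: i for i, b in enumerate(birds)}
    unknown = set(seq) - set(birds)
    if unknown:
        raise ValueError(f"sequence contains unknown birds {sorted(unknown)}")
    counts = np.zeros((len(birds), len(birds)), dtype=np.int64)
    if len(seq) < 2:
        warnings.warn("caller sequence shorter than 2: transition matrix is undefined")
        return TransitionMatrix(birds, counts)
    for a, b in zip(seq, seq[1:]):
        counts[index[a], index[b]] += 1
    return TransitionMatrix(birds, counts)


@dataclass
class AcousticNetwork:
    """Complete undirected weighted graph over the group's birds.

    ``weights`` maps each sorted dyad tuple to a finite weight or NaN
    (undefined, e.g. a silent bird's correlations).
    """

    nodes: list[str]
    weights: dict[tuple[str, str], float]
    weight_type: str
    node_meta: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.nodes)
        expected = {tuple(sorted((a, b))) for i, a in enumerate(self.nodes) for b in self.nodes[i + 1 :]}
        if set(self.weights) != expected:
            raise ValueError("weights must cover exactly every unordered dyad")
        for dyad, w in self.weights.items():
            if math.isnan(w):
                continue
            if self.weight_type == WEIGHT_CC and not -1.0 - 1e-12 <= w <= 1.0 + 1e-12:
                raise ValueError(f"cross-correlation weight out of range for {dyad}: {w}")
            if self.weight_type == WEIGHT_MAX_TRANSITION and not 0.0 <= w <= 1.0 + 1e-12:
                raise ValueError(f"transition weight out of range for {dyad}: {w}")

    def weight(self, a: str, b: str) -> float:
        return self.weights[tuple(sorted((a, b)))]

    def to_networkx(self, drop_undefined: bool = False):
        import networkx as nx

        g = nx.Graph(weight_type=self.weight_type)
        for n in self.nodes:
            g.add_node(n, **self.node_meta.get(n, {}))
        for (a, b), w in self.weights.items():
            if drop_undefined and math.isnan(w):
                continue
            g.add_edge(a, b, weight=w)
        return g


def max_transition_edges(matrix: TransitionMatrix) -> AcousticNetwork:
    """Dyad weights ``max(p(i->j), p(j->i))`` from a transition matrix.

    An undefined (NaN) direction is treated as absent; the dyad is
    undefined only when both directions are.  Diagonal entries never
    contribute.
    """
    birds = list(matrix.birds)
    if len(birds) < 2:
        raise ValueError("need at least 2 birds")
    weights = {}
    for i, a in enumerate(birds):
        for j in range(i + 1, len(birds)):
            b = birds[j]
            vals = [v for v in (matrix.probs[i, j], matrix.probs[j, i]) if not math.isnan(v)]
            weights[tuple(sorted((a, b)))] = max(vals) if vals else float("nan")
    return AcousticNetwork(nodes=birds, weights=weights, weight_type=WEIGHT_MAX_TRANSITION)


def build_transition_network(table: EventTable, birds) -> tuple[TransitionMatrix, AcousticNetwork]:
    """Caller sequence -> transition matrix -> max-transition network."""
    matrix = estimate_transition_matrix(caller_sequence(table), tuple(birds))
    return matrix, max_transition_edges(matrix)


def build_cc_network(
    table: EventTable,
    birds,
    duration_s: float,
    bin_width_s: float = DEFAULT_BIN_WIDTH_S,
    onset_only: bool = False,
) -> AcousticNetwork:
    """Cross-correlation network over all dyads of ``birds``."""
    birds = list(birds)
    if len(birds) < 2:
        raise ValueError("need at least 2 birds")
    signals = {b: binarize(table, b, duration_s, bin_width_s, onset_only=onset_only) for b in birds}
    weights = {}
    for i, a in enumerate(birds):
        for j in range(i + 1, len(birds)):
            b = birds[j]
            weights[tuple(sorted((a, b)))] = cross_correlation(signals[a], signals[b])
    return AcousticNetwork(nodes=birds, weights=weights, weight_type=WEIGHT_CC)
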